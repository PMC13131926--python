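"""PDB reading and writing for loops and macrocycles (via gemmi).

Conventions: single chain ``A``; residues numbered from 1; D-amino acids
use their standard 3-letter codes (DAL, DPR, DPN, ...); norleucine is NLE
(DNE for the D form); the N-methyl carbon is written as an extra backbone
atom ``CN`` on the amide nitrogen; ring closure is recorded as an explicit
LINK record between the last residue's C and the first residue's N.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np

from .geometry import BackboneResidueCoords, measure_torsions
from .model import Macrocycle, ResidueSpec
from .sampling import Loop

__all__ = ["PdbError", "write_pdb", "read_pdb", "read_macrocycle", "RING_CLOSURE_TOLERANCE"]

#: maximum last-C to first-N distance (A) for a file read as cyclic
RING_CLOSURE_TOLERANCE = 2.0


class PdbError(ValueError):
    pass


_L_NAMES = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "NLE",
}
_D_NAMES = {
    "A": "DAL", "R": "DAR", "N": "DSG", "D": "DAS", "C": "DCY",
    "Q": "DGN", "E": "DGL", "H": "DHI", "I": "DIL", "L": "DLE",
    "K": "DLY", "M": "MED", "F": "DPN", "P": "DPR", "S": "DSN",
    "T": "DTH", "W": "DTR", "Y": "DTY", "V": "DVA",
    "X": "DNE",  # D-norleucine, by this package's convention
}
_NAME_TO_SPEC: dict[str, tuple[str, str]] = {}
for aa, name in _L_NAMES.items():
    _NAME_TO_SPEC[name] = (aa, "achiral" if aa == "G" else "L")
for aa, name in _D_NAMES.items():
    _NAME_TO_SPEC[name] = (aa, "D")


def _residue_name(spec: ResidueSpec) -> str:
    table = _D_NAMES if spec.chirality == "D" else _L_NAMES
    try:
        return table[spec.aa]
    except KeyError:  # pragma: no cover - ResidueSpec validates identities
        raise PdbError(f"unsupported residue {spec.aa}")


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H", "CN": "C"}


def write_pdb(
    path: str | Path,
    obj: Macrocycle | Loop | None = None,
    *,
    specs: Sequence[ResidueSpec] | None = None,
    coords: Sequence[BackboneResidueCoords] | None = None,
    cyclic: bool | None = None,
) -> None:
    """Write a macrocycle or loop as a single-chain PDB file.

    Pass either a :class:`Macrocycle` (written cyclic, with a closure LINK
    record), a :class:`Loop` (written open), or explicit ``specs`` +
    ``coords`` with a ``cyclic`` flag.
    """
    if isinstance(obj, Macrocycle):
        if obj.coords is None:
            raise PdbError("no conformer")
        specs, coords = obj.residues, obj.coords
        cyclic = True if cyclic is None else cyclic
    elif isinstance(obj, Loop):
        specs = [ResidueSpec("G", "achiral", r.n_alkylated) for r in obj.residues]
        coords = obj.residues
        cyclic = False if cyclic is None else cyclic
    if specs is None or coords is None or cyclic is None:
        raise PdbError("need a Macrocycle, a Loop, or specs+coords+cyclic")
    if len(specs) != len(coords):
        raise PdbError("specs and coordinates differ in length")

    st = gemmi.Structure()
    st.name = "cyclopept"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (spec, rc) in enumerate(zip(specs, coords), start=1):
        res = gemmi.Residue()
        res.name = _residue_name(spec)
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "A"
        atoms = [("N", rc.n), ("CA", rc.ca), ("C", rc.c), ("O", rc.o)]
        if rc.h is not None:
            atoms.append(("H", rc.h))
        if rc.cm is not None:
            atoms.append(("CN", rc.cm))
        for name, pos in atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(_ELEMENTS[name])
            at.pos = gemmi.Position(*np.round(np.asarray(pos, float), 3))
            at.occ = 1.0
            at.b_iso = 0.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    if cyclic:
        con = gemmi.Connection()
        con.name = "ring"
        con.type = gemmi.ConnectionType.Covale
        last = len(specs)
        con.partner1 = gemmi.AtomAddress("A", gemmi.SeqId(last, " "), _residue_name(specs[-1]), "C", "\0")
        con.partner2 = gemmi.AtomAddress("A", gemmi.SeqId(1, " "), _residue_name(specs[0]), "N", "\0")
        st.connections.append(con)
    st.setup_entities()
    st.write_pdb(str(path))


def read_pdb(
    path: str | Path,
    topology: Literal["open", "cyclic"] = "open",
) -> tuple[list[ResidueSpec], list[BackboneResidueCoords]]:
    """Read a single-chain backbone PDB written by this package (or a
    compatible dialect) into residue specs and backbone coordinates.

    For cyclic topology the last-C to first-N distance is validated; a gap
    larger than :data:`RING_CLOSURE_TOLERANCE` triggers a "ring not
    closed" warning.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise PdbError("empty file")
    model = st[0]
    chains = [ch for ch in model]
    if len(chains) != 1:
        raise PdbError("single chain expected")
    specs: list[ResidueSpec] = []
    coords: list[BackboneResidueCoords] = []
    for res in chains[0]:
        if res.name not in _NAME_TO_SPEC:
            raise PdbError(f"unsupported residue {res.name}")
        aa, chirality = _NAME_TO_SPEC[res.name]
        atom = {}
        for at in res:
            atom[at.name.upper()] = np.array([at.pos.x, at.pos.y, at.pos.z])
        for needed in ("N", "CA", "C", "O"):
            if needed not in atom:
                raise PdbError(f"incomplete backbone: residue {res.seqid.num} lacks {needed}")
        alkylated = "CN" in atom or aa == "P"
        specs.append(ResidueSpec(aa, chirality, alkylated))
        coords.append(
            BackboneResidueCoords(
                n=atom["N"], ca=atom["CA"], c=atom["C"], o=atom["O"],
                h=atom.get("H") if not alkylated else None,
                cm=atom.get("CN"),
            )
        )
    if not coords:
        raise PdbError("empty chain")
    tor = measure_torsions(coords, topology=topology)
    for rc, (phi, psi, omega) in zip(coords, tor):
        rc.phi, rc.psi, rc.omega = float(phi), float(psi), float(omega)
    if topology == "cyclic":
        gap = float(np.linalg.norm(coords[-1].c - coords[0].n))
        if gap > RING_CLOSURE_TOLERANCE:
            warnings.warn(f"ring not closed: last-C to first-N distance {gap:.2f} A")
    return specs, coords


def read_macrocycle(path: str | Path) -> Macrocycle:
    """Read a cyclic PDB file into a :class:`Macrocycle`."""
    specs, coords = read_pdb(path, topology="cyclic")
    return Macrocycle(residues=specs, coords=coords)
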