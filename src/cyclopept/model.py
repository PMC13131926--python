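"""Macrocycle data model, sequence notation, and conformer audits.

Sequence notation: one letter per residue over the 20 canonical amino acids
plus X for norleucine; capital letters are L amino acids, lowercase are D;
glycine is achiral (written ``G``); a ``*`` after a letter marks backbone
N-methylation of that residue.  Proline's nitrogen is alkylated by its ring
regardless of ``*``.  Example: ``apL*F*apL*F*`` is an 8-residue ring of
D-Ala, D-Pro, N-Me-L-Leu, N-Me-L-Phe repeated twice — a C2-symmetric
sequence whose only backbone N-H donors sit at the two D-Ala positions.

Audits operate on a ring's backbone coordinates: unsatisfied-donor count
(the membrane-permeability heuristic: a structured macrocycle with every
amide N-H hydrogen bonded or methylated away tends to be permeable), cis
amide count, ABEGO torsion-bin strings and hydrogen-bond strings for
clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .geometry import (
    BackboneResidueCoords,
    HBond,
    HBondCriteria,
    detect_hbonds,
    measure_torsions,
)

__all__ = [
    "ResidueSpec",
    "Macrocycle",
    "ConformerStrings",
    "NotationError",
    "parse_sequence",
    "write_sequence",
    "cyclic_symmetry_order",
    "nh_satisfaction_audit",
    "count_cis_amides",
    "conformer_strings",
    "cluster_macrocycles",
    "abego_letter",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
NORLEUCINE = "X"


class NotationError(ValueError):
    pass


class AuditError(ValueError):
    pass


Chirality = Literal["L", "D", "achiral"]


@dataclass(frozen=True)
class ResidueSpec:
    """Chemical identity of one ring residue.

    ``aa`` is the one-letter code (uppercase; ``X`` = norleucine),
    ``chirality`` is L/D/achiral (glycine only), and ``n_alkylated`` marks a
    tertiary backbone nitrogen (N-methylation, or proline's ring).
    """

    aa: str
    chirality: Chirality
    n_alkylated: bool

    def __post_init__(self) -> None:
        if self.aa not in CANONICAL_AA and self.aa != NORLEUCINE:
            raise NotationError(f"unknown amino acid {self.aa!r}")
        if self.aa == "G" and self.chirality != "achiral":
            raise NotationError("glycine is achiral")
        if self.aa != "G" and self.chirality == "achiral":
            raise NotationError(f"{self.aa} requires L or D chirality")
        if self.aa == "P" and not self.n_alkylated:
            raise NotationError("proline's backbone nitrogen is always alkylated")


def parse_sequence(notation: str) -> list[ResidueSpec]:
    """Parse a macrocycle sequence string into residue specs.

    Raises :class:`NotationError` with the 1-based position of the first
    offending character.
    """
    if not notation:
        raise NotationError("notation error: empty sequence")
    specs: list[ResidueSpec] = []
    for pos, ch in enumerate(notation, start=1):
        if ch == "*":
            if not specs or notation[pos - 2] == "*":
                raise NotationError(f"notation error at position {pos}: '*' must follow a residue letter")
            prev = specs[-1]
            specs[-1] = ResidueSpec(prev.aa, prev.chirality, True)
            continue
        if not ch.isalpha():
            raise NotationError(f"notation error at position {pos}: unknown character {ch!r}")
        upper = ch.upper()
        if upper not in CANONICAL_AA and upper != NORLEUCINE:
            raise NotationError(f"notation error at position {pos}: unknown residue {ch!r}")
        if upper == "G":
            chirality: Chirality = "achiral"
        else:
            chirality = "L" if ch.isupper() else "D"
        specs.append(ResidueSpec(upper, chirality, upper == "P"))
    return specs


def write_sequence(residues: Sequence[ResidueSpec]) -> str:
    """Inverse of :func:`parse_sequence`.

    Glycine is written uppercase ``G`` by convention; an explicit ``*`` is
    emitted for every N-methylated residue except proline (whose alkylation
    is implied by the ring).
    """
    if not residues:
        raise NotationError("unencodable: empty residue list")
    out = []
    for r in residues:
        letter = r.aa if r.chirality != "D" else r.aa.lower()
        out.append(letter)
        if r.n_alkylated and r.aa != "P":
            out.append("*")
    return "".join(out)


def cyclic_symmetry_order(residues: Sequence[ResidueSpec]) -> int:
    """Largest k dividing the ring length such that rotation by length/k
    maps the sequence (identity, chirality, alkylation) onto itself."""
    L = len(residues)
    if L < 1:
        raise NotationError("empty ring")
    for k in range(L, 0, -1):
        if L % k != 0:
            continue
        shift = L // k
        if all(residues[i] == residues[(i + shift) % L] for i in range(L)):
            return k
    return 1


@dataclass
class Macrocycle:
    """A head-to-tail cyclised peptide: ring of residue specs, optional
    backbone coordinates, and its transannular hydrogen bonds."""

    residues: list[ResidueSpec]
    coords: list[BackboneResidueCoords] | None = None
    transannular_hbonds: list[HBond] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    closure_rmsd: float = math.nan

    def __post_init__(self) -> None:
        if len(self.residues) < 5:
            raise NotationError("ring length must be at least 5")
        if self.coords is not None and len(self.coords) != len(self.residues):
            raise NotationError("coordinates do not match ring length")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return write_sequence(self.residues)

    def refresh_torsions(self) -> None:
        """Re-measure phi/psi/omega from coordinates (cyclic topology)."""
        if self.coords is None:
            raise AuditError("no conformer")
        tor = measure_torsions(self.coords, topology="cyclic")
        for r, (phi, psi, omega) in zip(self.coords, tor):
            r.phi, r.psi, r.omega = float(phi), float(psi), float(omega)

    def with_sequence(self, residues: Sequence[ResidueSpec] | str) -> "Macrocycle":
        """Attach a designed sequence to this backbone.

        The sequence's N-alkylation pattern must match the backbone's (up
        to ring rotation it is the caller's job to pre-align; positions are
        matched index-wise)."""
        specs = parse_sequence(residues) if isinstance(residues, str) else list(residues)
        if len(specs) != len(self.residues):
            raise NotationError("sequence length does not match ring length")
        if self.coords is not None:
            for i, (s, r) in enumerate(zip(specs, self.coords)):
                if s.n_alkylated != r.n_alkylated:
                    raise NotationError(
                        f"alkylation mismatch at position {i + 1}: sequence vs backbone"
                    )
        return Macrocycle(
            residues=specs,
            coords=self.coords,
            transannular_hbonds=list(self.transannular_hbonds),
            provenance=dict(self.provenance),
            closure_rmsd=self.closure_rmsd,
        )


def nh_satisfaction_audit(mc: Macrocycle, criteria: HBondCriteria = HBondCriteria()) -> int:
    """Number of backbone N-H donors not engaged in a backbone hydrogen bond.

    N-alkylated residues and prolines have no donor and never count.  Zero
    means every amide proton is satisfied — the design heuristic for
    passive membrane permeability.
    """
    if mc.coords is None:
        raise AuditError("no conformer")
    bonds = detect_hbonds(mc.coords, criteria, topology="cyclic")
    donating = {b.donor for b in bonds}
    unsat = 0
    for i, (spec, res) in enumerate(zip(mc.residues, mc.coords)):
        if spec.n_alkylated or spec.aa == "P" or res.h is None:
            continue
        if i not in donating:
            unsat += 1
    return unsat


def count_cis_amides(mc: Macrocycle) -> int:
    """Ring amides in the cis conformation (|omega| < 90 deg)."""
    if mc.coords is None:
        raise AuditError("no conformer")
    omegas = measure_torsions(mc.coords, topology="cyclic")[:, 2]
    return int(np.sum(np.abs(omegas) < 90.0))


def abego_letter(phi: float, psi: float, omega: float) -> str:
    """Backbone torsion-bin classification.

    O overrides for cis amides; otherwise A (alpha, phi<0, -75<=psi<50),
    B (beta, other phi<0), G (positive-phi alpha mirror, -100<=psi<100),
    E (other phi>=0).
    """
    if abs(omega) < 90.0:
        return "O"
    if phi < 0.0:
        return "A" if -75.0 <= psi < 50.0 else "B"
    return "G" if -100.0 <= psi < 100.0 else "E"


@dataclass(frozen=True)
class ConformerStrings:
    """Rotation-canonicalised ABEGO and hydrogen-bond strings of a ring."""

    abego: str
    hbond_string: str
    rotation: int  # offset applied to canonicalise (original index of new residue 1)


def _hbond_string_at_rotation(bonds: list[HBond], L: int, rot: int) -> str:
    entries = sorted(((b.donor - rot) % L, (b.acceptor - rot) % L) for b in bonds)
    return ",".join(f"{d}>{a}" for d, a in entries)


def conformer_strings(mc: Macrocycle, criteria: HBondCriteria = HBondCriteria()) -> ConformerStrings:
    """ABEGO string and transannular hydrogen-bond string, canonicalised to
    the lexicographically smallest rotation (the same rotation is applied
    to both strings; ties break on the smallest rotation index)."""
    if mc.coords is None:
        raise AuditError("no conformer")
    tor = measure_torsions(mc.coords, topology="cyclic")
    letters = [abego_letter(*t) for t in tor]
    L = len(letters)
    bonds = mc.transannular_hbonds or detect_hbonds(mc.coords, criteria, topology="cyclic")
    best: tuple[str, str, int] | None = None
    for rot in range(L):
        ab = "".join(letters[(i + rot) % L] for i in range(L))
        hb = _hbond_string_at_rotation(bonds, L, rot)
        cand = (ab, hb, rot)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return ConformerStrings(abego=best[0], hbond_string=best[1], rotation=best[2])


def cluster_macrocycles(
    mcs: Sequence[Macrocycle],
    score: Callable[[Macrocycle], float] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> dict[tuple[str, str], dict]:
    """Partition macrocycles by (ABEGO, hydrogen-bond string) and pick one
    representative per cluster.

    The representative minimises ``score`` (default: closure rmsd, i.e. the
    cleanest ring closure), with deterministic tie-breaking on the member's
    index.  Returns a mapping cluster key -> {"members": [...indices...],
    "representative": index}.
    """
    if score is None:
        score = lambda m: m.closure_rmsd if math.isfinite(m.closure_rmsd) else 0.0
    clusters: dict[tuple[str, str], dict] = {}
    for idx, mc in enumerate(mcs):
        cs = conformer_strings(mc, criteria)
        key = (cs.abego, cs.hbond_string)
        entry = clusters.setdefault(key, {"members": [], "representative": None})
        entry["members"].append(idx)
    for key, entry in clusters.items():
        entry["representative"] = min(entry["members"], key=lambda i: (score(mcs[i]), i))
    return clusters
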