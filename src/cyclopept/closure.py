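"""Ring closure by 6D-transform geometric hashing.

Each loop carries the rigid transform between its terminal NCaC frames in
both senses (N-to-C and C-to-N).  Transforms are binned into integer keys
(translation bins in angstroms, orientation bins on the rotation's
axis-angle vector in degrees) and stored in a hash table.  Two loops can be
fused into a closed macrocycle when the N-to-C key of one equals the C-to-N
key of the other; a loop whose own forward and reverse keys coincide closes
on a second copy of itself, yielding a C2-symmetric ring.

Fusion overlays the terminal glycines of the two loops (each loop's
N-terminus onto the other's C-terminus) and merges the overlapped residues,
keeping the first loop's coordinates for the shared positions.  Because the
two terminal frames only match to within the bin tolerance, the merged ring
is then re-closed in torsion space: its measured phi/psi torsions are
adjusted by cyclic coordinate descent (CCD) until the ring closure gap
vanishes, and the ring is rebuilt at ideal covalent geometry.  The closed
ring is audited for peptide-bond geometry, steric clashes, and the
presence of exactly two transannular backbone hydrogen bonds between the
junction residues.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BackboneResidueCoords,
    HBondCriteria,
    RigidTransform,
    build_backbone_arrays,
    detect_hbonds,
    find_clashes,
    measure_torsions,
    replace_amide_hydrogens,
    superpose,
)
from .model import Macrocycle, ResidueSpec
from .sampling import Loop

__all__ = [
    "BinWidths",
    "TransformKey",
    "ClosurePair",
    "ClosureTolerances",
    "ClosureError",
    "transform_key",
    "transform_keys",
    "index_library",
    "find_closures",
    "fuse",
    "symmetrize_c2",
    "c2_operator",
    "close_library",
    "close_ring_torsions",
    "terminal_alignment",
]


class ClosureError(ValueError):
    pass


@dataclass(frozen=True)
class BinWidths:
    """Bin widths for the 6D transform hash.

    Translation components are floored into ``translation``-angstrom bins;
    the rotation's axis-angle vector components into ``orientation_deg``
    bins.  Bins are left-closed with edges at integer multiples of the
    width, so the identity transform maps to the all-zero key.
    """

    translation: float = 1.0
    orientation_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.translation <= 0 or self.orientation_deg <= 0:
            raise ClosureError("invalid binning: widths must be positive")


TransformKey = tuple[int, int, int, int, int, int]


def transform_key(t: RigidTransform, bins: BinWidths = BinWidths()) -> TransformKey:
    """Hash key of a rigid transform: floor-binned translation and
    axis-angle orientation components."""
    tr = np.floor(t.translation / bins.translation).astype(int)
    rv = np.floor(t.rotvec_deg() / bins.orientation_deg).astype(int)
    return tuple(tr) + tuple(rv)


def transform_keys(t: RigidTransform, bins: BinWidths = BinWidths()) -> list[TransformKey]:
    """Keys of a transform including the antipodal axis-angle representation.

    The axis-angle map is discontinuous at a rotation angle of 180 deg: a
    near-involution can be represented by rotvec ``theta * a`` or by the
    equivalent ``(theta - 360) * a``.  Within one orientation bin of 180 deg
    both representations are emitted so that near-C2 transforms hash
    consistently on either side of the cut.
    """
    keys = [transform_key(t, bins)]
    rv = t.rotvec_deg()
    theta = float(np.linalg.norm(rv))
    if theta > 1e-12 and theta >= 180.0 - bins.orientation_deg:
        rv_alt = rv * (theta - 360.0) / theta
        tr = tuple(np.floor(t.translation / bins.translation).astype(int))
        alt = tr + tuple(np.floor(rv_alt / bins.orientation_deg).astype(int))
        if alt != keys[0]:
            keys.append(alt)
    return keys


def _neighbor_keys(key: TransformKey) -> list[TransformKey]:
    deltas = itertools.product((-1, 0, 1), repeat=6)
    return [tuple(k + d for k, d in zip(key, delta)) for delta in deltas]


@dataclass(frozen=True)
class ClosurePair:
    """A key-matched pair of loops (i may equal j for C2 self-closure)."""

    loop_i: str
    loop_j: str
    key: TransformKey
    terminal_rmsd: float


@dataclass(frozen=True)
class ClosureTolerances:
    terminal_rmsd: float = 0.5  # A, on the 6 junction backbone atoms
    bond_length: float = 0.1  # A, allowed deviation of ring C-N bonds from 1.329
    clash_radius: float = 2.8  # A, heavy atoms in non-adjacent residues
    ccd_gap: float = 0.03  # A, target rmsd of the CCD ring-closure gap
    ccd_max_sweeps: int = 200


@dataclass
class HashTable:
    """Transform-key hash table over a loop library.

    ``forward`` and ``reverse`` map each key to the loop ids whose N-to-C
    (resp. C-to-N) transform falls in that bin; every loop contributes both
    senses.
    """

    forward: dict[TransformKey, list[str]] = field(default_factory=dict)
    reverse: dict[TransformKey, list[str]] = field(default_factory=dict)
    loops: dict[str, Loop] = field(default_factory=dict)
    bins: BinWidths = field(default_factory=BinWidths)

    def n_entries(self) -> int:
        return 2 * len(self.loops)


def index_library(loops: list[Loop] | "object", bins: BinWidths = BinWidths()) -> HashTable:
    """Hash every loop's terminal transform in both senses."""
    table = HashTable(bins=bins)
    for loop in loops:
        if loop.loop_id in table.loops:
            raise ClosureError(f"id collision: {loop.loop_id}")
        table.loops[loop.loop_id] = loop
        for key in transform_keys(loop.forward_transform, bins):
            table.forward.setdefault(key, []).append(loop.loop_id)
        for key in transform_keys(loop.reverse_transform, bins):
            table.reverse.setdefault(key, []).append(loop.loop_id)
    if not table.loops:
        raise ClosureError("empty library")
    return table


def terminal_alignment(loop_i: Loop, loop_j: Loop) -> tuple[RigidTransform, float]:
    """Superpose loop_j's terminal glycines onto loop_i's, N onto C and C
    onto N, using the 6 backbone N/CA/C atoms of the two terminal residues."""
    ji, jj = loop_j.residues[0], loop_j.residues[-1]
    ii, ij = loop_i.residues[-1], loop_i.residues[0]
    mobile = np.array([ji.n, ji.ca, ji.c, jj.n, jj.ca, jj.c])
    target = np.array([ii.n, ii.ca, ii.c, ij.n, ij.ca, ij.c])
    return superpose(mobile, target)


def find_closures(table: HashTable, neighbor_bins: bool = False) -> list[ClosurePair]:
    """All loop pairs whose N-to-C and C-to-N keys match.

    Self-pairs (i == j) are included — they yield C2-symmetric rings.
    Pairs are unique up to order and sorted by (terminal rmsd, ids).  With
    ``neighbor_bins`` the query also probes the 3^6 adjacent bins, catching
    matches split across bin edges.
    """
    seen: set[tuple[str, str]] = set()
    pairs: list[ClosurePair] = []
    for key, fwd_ids in table.forward.items():
        queries = _neighbor_keys(key) if neighbor_bins else [key]
        rev_ids = sorted({i for q in queries for i in table.reverse.get(q, [])})
        for fid in fwd_ids:
            for rid in rev_ids:
                pair_id = (min(fid, rid), max(fid, rid))
                if pair_id in seen:
                    continue
                seen.add(pair_id)
                _, rmsd = terminal_alignment(table.loops[fid], table.loops[rid])
                pairs.append(ClosurePair(fid, rid, key, rmsd))
    pairs.sort(key=lambda p: (p.terminal_rmsd, p.loop_i, p.loop_j))
    return pairs


def _ring_specs(residues: list[BackboneResidueCoords]) -> list[ResidueSpec]:
    # backbone-stage rings are polyglycine/sarcosine
    return [ResidueSpec(aa="G", chirality="achiral", n_alkylated=r.n_alkylated) for r in residues]


def _check_ring_bonds(residues: list[BackboneResidueCoords], tol: ClosureTolerances) -> None:
    ideal = 1.329
    L = len(residues)
    for i in range(L):
        d = float(np.linalg.norm(residues[i].c - residues[(i + 1) % L].n))
        if abs(d - ideal) > tol.bond_length:
            raise ClosureError(f"closure failure: ring C-N bond {i}->{(i + 1) % L} is {d:.2f} A")


def _check_clashes(residues: list[BackboneResidueCoords], tol: ClosureTolerances, criteria: HBondCriteria) -> None:
    clashes = find_clashes(residues, tol.clash_radius, topology="cyclic", criteria=criteria)
    if clashes:
        i, j = clashes[0]
        raise ClosureError(f"steric rejection: residues {i} and {j}")


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    v = points - origin
    ct, st = math.cos(theta), math.sin(theta)
    return origin + v * ct + np.cross(u, v) * st + np.outer(v @ u, u) * (1.0 - ct)


def close_ring_torsions(
    torsions: np.ndarray,
    gap_tol: float = 0.03,
    max_sweeps: int = 200,
) -> tuple[np.ndarray, float, int]:
    """Close a ring in torsion space by cyclic coordinate descent.

    ``torsions`` is an (L, 3) array of phi/psi/omega for a ring whose
    measured torsions nearly, but not exactly, satisfy ring closure.  The
    chain is rebuilt at ideal covalent geometry with a duplicated first
    residue at the end; phi/psi torsions (omegas stay fixed) are adjusted
    one at a time, each rotation chosen in closed form to minimise the
    distance between the duplicated and the anchor N/CA/C atoms.

    Returns the adjusted (L, 3) torsions, the residual gap rmsd (A) and the
    number of CCD sweeps used.
    """
    torsions = np.asarray(torsions, float)
    L = torsions.shape[0]
    phi = np.append(torsions[:, 0], torsions[0, 0])
    psi = np.append(torsions[:, 1], torsions[0, 1])
    omega = np.append(torsions[:, 2], torsions[0, 2])
    arrs = build_backbone_arrays(phi, psi, omega)
    # flat atom array in NeRF order: N_k, CA_k, C_k for k = 0..L
    atoms = np.empty((3 * (L + 1), 3))
    atoms[0::3] = arrs["N"]
    atoms[1::3] = arrs["CA"]
    atoms[2::3] = arrs["C"]
    target = atoms[:3].copy()  # anchor N1, CA1, C1

    def gap() -> float:
        mov = atoms[3 * L : 3 * L + 3]
        return float(np.sqrt(((mov - target) ** 2).sum(axis=1).mean()))

    def best_theta(origin: np.ndarray, tip: np.ndarray) -> float:
        # closed-form optimal rotation for the three end atoms (CCD step)
        u = tip - origin
        u = u / np.linalg.norm(u)
        num = den = 0.0
        for m, t in zip(atoms[3 * L : 3 * L + 3], target):
            o = origin + u * (u @ (m - origin))
            rv = m - o
            r2 = float(np.linalg.norm(rv))
            if r2 < 1e-9:
                continue
            rhat = rv / r2
            shat = np.cross(u, rhat)
            f = t - o
            den += r2 * float(f @ rhat)
            num += r2 * float(f @ shat)
        return math.atan2(num, den)

    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        if gap() < gap_tol:
            sweeps -= 1
            break
        for k in range(L):
            # psi_k rotates everything from N_{k+1} onward about CA_k - C_k
            th = best_theta(atoms[3 * k + 1], atoms[3 * k + 2])
            atoms[3 * (k + 1):] = _rotate_about_axis(atoms[3 * (k + 1):], atoms[3 * k + 1], atoms[3 * k + 2] - atoms[3 * k + 1], th)
            psi[k] = (psi[k] + math.degrees(th) + 180.0) % 360.0 - 180.0
            if k >= 1:
                # phi_k rotates everything from C_k onward about N_k - CA_k
                th = best_theta(atoms[3 * k], atoms[3 * k + 1])
                atoms[3 * k + 2:] = _rotate_about_axis(atoms[3 * k + 2:], atoms[3 * k], atoms[3 * k + 1] - atoms[3 * k], th)
                phi[k] = (phi[k] + math.degrees(th) + 180.0) % 360.0 - 180.0
    return np.column_stack([phi[:L], psi[:L], omega[:L]]), gap(), sweeps


def fuse(
    loop_i: Loop,
    loop_j: Loop,
    criteria: HBondCriteria = HBondCriteria(),
    tolerances: ClosureTolerances = ClosureTolerances(),
    symmetrize: bool = True,
) -> Macrocycle:
    """Fuse two loops into a closed macrocycle.

    A copy of ``loop_j`` is aligned with its terminal glycines swapped onto
    ``loop_i``'s; the overlapped terminals are merged keeping ``loop_i``'s
    coordinates, giving a ring of len(i) + len(j) - 2 residues.  The merged
    ring's torsions are then re-closed exactly by CCD and the ring rebuilt
    at ideal covalent geometry.  The ring is rejected unless the terminal
    superposition, the CCD gap and the junction bonds are within tolerance,
    no steric clash remains, and exactly two transannular backbone hydrogen
    bonds are present.  Self-fusions are C2-symmetrized when ``symmetrize``
    is set.
    """
    transform, rmsd = terminal_alignment(loop_i, loop_j)
    if rmsd > tolerances.terminal_rmsd:
        raise ClosureError(f"closure failure: terminal rmsd {rmsd:.2f} A")
    rough = [r.copy() for r in loop_i.residues]
    rough += [r.moved_by(transform) for r in loop_j.residues[1:-1]]
    alkylated = [r.n_alkylated for r in rough]
    torsions = measure_torsions(rough, topology="cyclic")
    closed, gap, _ = close_ring_torsions(torsions, tolerances.ccd_gap, tolerances.ccd_max_sweeps)
    if gap > tolerances.ccd_gap * 2:
        raise ClosureError(f"closure failure: ring gap {gap:.2f} A after CCD")
    arrs = build_backbone_arrays(closed[:, 0], closed[:, 1], closed[:, 2])
    ring = [
        BackboneResidueCoords(
            n=arrs["N"][k], ca=arrs["CA"][k], c=arrs["C"][k], o=arrs["O"][k],
            h=None if alk else arrs["H"][k],
            cm=arrs["CM"][k] if alk else None,
        )
        for k, alk in enumerate(alkylated)
    ]
    replace_amide_hydrogens(ring, topology="cyclic")
    _check_ring_bonds(ring, tolerances)
    _check_clashes(ring, tolerances, criteria)
    mc = Macrocycle(
        residues=_ring_specs(ring),
        coords=ring,
        transannular_hbonds=[],
        provenance={"loop_i": loop_i.loop_id, "loop_j": loop_j.loop_id},
        closure_rmsd=rmsd,
    )
    mc.refresh_torsions()
    if symmetrize and loop_i.loop_id == loop_j.loop_id:
        mc = symmetrize_c2(mc)
    hbonds = detect_hbonds(mc.coords, criteria, topology="cyclic")
    if len(hbonds) != 2:
        raise ClosureError(f"closure failure: {len(hbonds)} transannular hydrogen bonds (need 2)")
    mc.transannular_hbonds = hbonds
    return mc


def _residue_atom_stack(residues: list[BackboneResidueCoords]) -> np.ndarray:
    out = []
    for r in residues:
        out += [r.n, r.ca, r.c, r.o, r.h if r.h is not None else r.cm]
    return np.array(out)


def c2_operator(mc: Macrocycle) -> RigidTransform:
    """Best-fit two-fold symmetry operator of a ring under the half-turn
    residue permutation, projected to an exact involution (rotation angle
    exactly pi, screw component removed)."""
    if mc.coords is None:
        raise ClosureError("no conformer")
    L = len(mc.coords)
    if L % 2 != 0:
        raise ClosureError("not C2-compatible: odd ring length")
    half = L // 2
    for i in range(L):
        if mc.coords[i].n_alkylated != mc.coords[(i + half) % L].n_alkylated:
            raise ClosureError("not C2-compatible: alkylation pattern breaks the half-turn map")
    perm = [(i + half) % L for i in range(L)]
    coords = _residue_atom_stack(mc.coords)
    coords_perm = _residue_atom_stack([mc.coords[p] for p in perm])
    t_fit, _ = superpose(coords_perm, coords)
    rv = t_fit.rotvec_deg()
    theta = np.linalg.norm(rv)
    if theta < 1e-6:
        raise ClosureError("not C2-compatible: fitted operator is close to identity")
    axis = rv / theta
    R = 2.0 * np.outer(axis, axis) - np.eye(3)  # rotation by pi about axis
    # drop the screw translation along the axis so that S o S = identity
    t_perp = t_fit.translation - axis * float(axis @ t_fit.translation)
    return RigidTransform(R, t_perp)


def symmetrize_c2(mc: Macrocycle) -> Macrocycle:
    """Project a self-fused ring onto exact C2 symmetry.

    The best-fit rigid motion mapping the ring onto its half-turn residue
    permutation is projected to an exact two-fold operator (rotation angle
    exactly 180 deg, screw component removed), and coordinates are averaged
    with their image.  The result is exactly invariant under the operator
    and the procedure is idempotent.
    """
    S = c2_operator(mc)
    L = len(mc.coords)
    half = L // 2
    perm = [(i + half) % L for i in range(L)]
    coords = _residue_atom_stack(mc.coords)
    coords_perm = _residue_atom_stack([mc.coords[p] for p in perm])
    sym = (coords + S.apply(coords_perm)) / 2.0
    new_res = []
    for i, r in enumerate(mc.coords):
        block = sym[5 * i : 5 * i + 5]
        new_res.append(
            BackboneResidueCoords(
                n=block[0], ca=block[1], c=block[2], o=block[3],
                h=None if r.n_alkylated else block[4],
                cm=block[4] if r.n_alkylated else None,
            )
        )
    out = Macrocycle(
        residues=list(mc.residues),
        coords=new_res,
        transannular_hbonds=[],
        provenance=dict(mc.provenance),
        closure_rmsd=mc.closure_rmsd,
    )
    out.refresh_torsions()
    return out


def close_library(
    loops,
    bins: BinWidths = BinWidths(),
    criteria: HBondCriteria = HBondCriteria(),
    tolerances: ClosureTolerances = ClosureTolerances(),
    neighbor_bins: bool = False,
) -> tuple[list[Macrocycle], list[dict]]:
    """End-to-end closure: hash the library, enumerate key-matched pairs,
    fuse each and keep the rings that pass every audit.

    Returns the macrocycles and a per-pair report (ids, key, rmsd, status).
    """
    table = index_library(loops, bins)
    pairs = find_closures(table, neighbor_bins=neighbor_bins)
    rings: list[Macrocycle] = []
    report: list[dict] = []
    for pair in pairs:
        row = {
            "loop_i": pair.loop_i,
            "loop_j": pair.loop_j,
            "key": pair.key,
            "terminal_rmsd": pair.terminal_rmsd,
        }
        try:
            mc = fuse(table.loops[pair.loop_i], table.loops[pair.loop_j], criteria, tolerances)
        except ClosureError as exc:
            row.update(status="rejected", reason=str(exc), hbond_count=None)
            report.append(row)
            continue
        row.update(status="closed", reason="", hbond_count=len(mc.transannular_hbonds))
        report.append(row)
        rings.append(mc)
    return rings, report
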