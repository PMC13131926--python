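"""Backbone geometry: rigid transforms, residue frames, torsion-driven
chain construction, superposition and backbone hydrogen-bond detection.

Conventions
-----------
* Units are angstroms and degrees; coordinate frames are right-handed.
* Torsions follow the IUPAC convention.  ``omega`` of residue *i* is the
  CA(i-1)-C(i-1)-N(i)-CA(i) dihedral; an amide is *cis* iff |omega| < 90.
* A residue frame ("NCaC frame") has its origin at the alpha-carbon with
  axes built from the backbone N, CA and carbonyl-C atoms; its columns map
  local coordinates to global ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "IDEAL_GEOMETRY",
    "RigidTransform",
    "ResidueFrame",
    "BackboneResidueCoords",
    "HBond",
    "HBondCriteria",
    "build_backbone",
    "measure_torsions",
    "frame_transform",
    "superpose",
    "detect_hbonds",
    "find_clashes",
    "dihedral",
    "angle_deg",
    "replace_amide_hydrogens",
]

#: Ideal backbone covalent geometry (angstroms / degrees).  These are the
#: standard small-molecule values used for torsion-space backbone builders.
IDEAL_GEOMETRY = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C=O": 1.231,
    "N-H": 1.010,
    "N-CH3": 1.455,
    "C-N-CA": 121.7,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "CA-C-O": 120.1,
}


class GeometryError(ValueError):
    """Raised for degenerate or invalid geometric input."""


# ---------------------------------------------------------------------------
# rigid transforms and frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t``.

    ``rotation`` is a 3x3 proper-orthonormal matrix, ``translation`` a
    3-vector in angstroms.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation is improper (determinant -1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def rotvec_deg(self) -> np.ndarray:
        """Axis-angle vector of the rotation part, in degrees."""
        return Rotation.from_matrix(self.rotation).as_rotvec(degrees=True)

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class ResidueFrame:
    """Orthonormal coordinate frame attached to one residue.

    ``origin`` sits on the alpha-carbon; ``axes`` columns are the basis
    vectors expressed in global coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    @classmethod
    def from_backbone(cls, n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> "ResidueFrame":
        n = np.asarray(n, float)
        ca = np.asarray(ca, float)
        c = np.asarray(c, float)
        e1 = n - ca
        norm1 = np.linalg.norm(e1)
        if norm1 < 1e-8:
            raise GeometryError("degenerate frame: N and CA coincide")
        e1 = e1 / norm1
        v = c - ca
        e3 = np.cross(e1, v)
        norm3 = np.linalg.norm(e3)
        if norm3 < 1e-8:
            raise GeometryError("degenerate frame: N, CA, C are collinear")
        e3 = e3 / norm3
        e2 = np.cross(e3, e1)
        return cls(ca.copy(), np.column_stack([e1, e2, e3]))

    def push(self, t: RigidTransform) -> "ResidueFrame":
        """Apply a transform expressed in *this* frame's local coordinates."""
        return ResidueFrame(self.origin + self.axes @ t.translation, self.axes @ t.rotation)

    def moved_by(self, t: RigidTransform) -> "ResidueFrame":
        """Apply a global rigid motion to the frame."""
        return ResidueFrame(t.apply(self.origin), t.rotation @ self.axes)


def frame_transform(a: ResidueFrame, b: ResidueFrame) -> RigidTransform:
    """Relative transform from frame ``a`` to frame ``b``.

    The result is expressed in ``a``'s local coordinates, so that
    ``a.push(frame_transform(a, b))`` reproduces ``b`` exactly.
    """
    return RigidTransform(a.axes.T @ b.axes, a.axes.T @ (b.origin - a.origin))


# ---------------------------------------------------------------------------
# residues and torsion measurement
# ---------------------------------------------------------------------------


@dataclass
class BackboneResidueCoords:
    """Backbone heavy atoms (plus the amide substituent) of one residue.

    Exactly one of ``h`` (amide hydrogen) and ``cm`` (N-methyl carbon) is
    present: tertiary amides carry no donor hydrogen.
    """

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: np.ndarray | None = None
    cm: np.ndarray | None = None
    phi: float = math.nan
    psi: float = math.nan
    omega: float = math.nan

    @property
    def n_alkylated(self) -> bool:
        return self.cm is not None

    def heavy_atoms(self) -> list[np.ndarray]:
        atoms = [self.n, self.ca, self.c, self.o]
        if self.cm is not None:
            atoms.append(self.cm)
        return atoms

    def frame(self) -> ResidueFrame:
        return ResidueFrame.from_backbone(self.n, self.ca, self.c)

    def moved_by(self, t: RigidTransform) -> "BackboneResidueCoords":
        return BackboneResidueCoords(
            n=t.apply(self.n),
            ca=t.apply(self.ca),
            c=t.apply(self.c),
            o=t.apply(self.o),
            h=None if self.h is None else t.apply(self.h),
            cm=None if self.cm is None else t.apply(self.cm),
            phi=self.phi,
            psi=self.psi,
            omega=self.omega,
        )

    def copy(self) -> "BackboneResidueCoords":
        return self.moved_by(RigidTransform.identity())


def _normalize(v: np.ndarray, axis: int = -1) -> np.ndarray:
    return v / np.linalg.norm(v, axis=axis, keepdims=True)


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC sign convention).

    Accepts arrays broadcast over leading dimensions.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _normalize(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def angle_deg(a, b, c) -> np.ndarray:
    """Angle a-b-c in degrees."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    u = _normalize(a - b)
    v = _normalize(c - b)
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _cross3(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    # manual cross product: avoids np.cross's axis-juggling overhead in the
    # hot NeRF path
    out = np.empty(np.broadcast(u, v).shape)
    out[..., 0] = u[..., 1] * v[..., 2] - u[..., 2] * v[..., 1]
    out[..., 1] = u[..., 2] * v[..., 0] - u[..., 0] * v[..., 2]
    out[..., 2] = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    return out


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.sqrt((v * v).sum(axis=-1, keepdims=True))


def place_atom(a, b, c, bond: float, angle: float, torsion) -> np.ndarray:
    """NeRF placement: new atom ``d`` with |c-d| = bond, angle(b,c,d) = angle
    and dihedral(a,b,c,d) = torsion (degrees).  Broadcasts over leading axes.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    torsion = np.asarray(torsion, float)
    bc = _unit(c - b)
    n = _unit(_cross3(b - a, bc))
    m = _cross3(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = (
        -np.cos(ang)[..., None] * bc
        + (np.sin(ang) * np.cos(tor))[..., None] * m
        + (np.sin(ang) * np.sin(tor))[..., None] * n
    )
    return c + bond * d_local


# Phantom anchor atoms seeding the NeRF recursion for residue 1: a canonical
# trans peptide placed in the z=0 plane.  Residue 1's phi/omega are realised
# against these anchors; for an open chain they are not measurable.
_G = IDEAL_GEOMETRY


def _phantom_anchor() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ca0 = np.zeros(3)
    c0 = np.array([_G["CA-C"], 0.0, 0.0])
    th = math.radians(_G["N-CA-C"])
    n0 = _G["N-CA"] * np.array([math.cos(th), math.sin(th), 0.0])
    return n0, ca0, c0


def _amide_substituent(c_prev: np.ndarray, n: np.ndarray, ca: np.ndarray, bond: float) -> np.ndarray:
    """Place the third substituent on a planar amide nitrogen: in the
    C(prev)-N-CA plane, opposite their bisector."""
    d = -(_unit(c_prev - n) + _unit(ca - n))
    return n + bond * _unit(d)


def build_backbone_arrays(
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorised chain builder.

    ``phi``, ``psi``, ``omega`` have shape (..., L); returns a dict of atom
    arrays of shape (..., L, 3).  The amide substituent arrays ``h`` and
    ``cm`` are filled for every residue (use ``alkylated`` to pick one).
    """
    phi = np.asarray(phi, float)
    psi = np.asarray(psi, float)
    omega = np.asarray(omega, float)
    L = phi.shape[-1]
    if L < 1:
        raise GeometryError("empty chain")
    for arr, nm in ((phi, "phi"), (psi, "psi"), (omega, "omega")):
        vals = arr[np.isfinite(arr)]
        if vals.size and (np.any(vals < -180.0) or np.any(vals > 180.0)):
            raise GeometryError(f"invalid torsion: {nm} outside [-180, 180]")
    lead = phi.shape[:-1]
    n0, ca0, c0 = _phantom_anchor()
    prev_n = np.broadcast_to(n0, lead + (3,))
    prev_ca = np.broadcast_to(ca0, lead + (3,))
    prev_c = np.broadcast_to(c0, lead + (3,))
    N = np.empty(lead + (L, 3))
    CA = np.empty_like(N)
    C = np.empty_like(N)
    O = np.empty_like(N)
    H = np.empty_like(N)
    CM = np.empty_like(N)
    psi_prev = np.full(lead, 180.0)
    for i in range(L):
        ni = place_atom(prev_n, prev_ca, prev_c, _G["C-N"], _G["CA-C-N"], psi_prev)
        cai = place_atom(prev_ca, prev_c, ni, _G["N-CA"], _G["C-N-CA"], omega[..., i])
        ci = place_atom(prev_c, ni, cai, _G["CA-C"], _G["N-CA-C"], phi[..., i])
        oi = place_atom(ni, cai, ci, _G["C=O"], _G["CA-C-O"],
                        np.where(np.isfinite(psi[..., i]), psi[..., i], 180.0) + 180.0)
        N[..., i, :] = ni
        CA[..., i, :] = cai
        C[..., i, :] = ci
        O[..., i, :] = oi
        H[..., i, :] = _amide_substituent(prev_c, ni, cai, _G["N-H"])
        CM[..., i, :] = _amide_substituent(prev_c, ni, cai, _G["N-CH3"])
        prev_n, prev_ca, prev_c = ni, cai, ci
        psi_prev = np.where(np.isfinite(psi[..., i]), psi[..., i], 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H, "CM": CM}


def build_backbone(
    torsions: Sequence[tuple[float, float, float]],
    alkylated: Sequence[bool] | None = None,
) -> list[BackboneResidueCoords]:
    """Build a chain from per-residue (phi, psi, omega) triples.

    ``alkylated[i]`` marks tertiary amide nitrogens (N-methyl); those
    residues carry an N-methyl carbon instead of the amide hydrogen.
    Residue 1 is placed in a canonical anchor frame at the origin.
    """
    torsions = list(torsions)
    if not torsions:
        raise GeometryError("empty chain")
    if alkylated is None:
        alkylated = [False] * len(torsions)
    if len(alkylated) != len(torsions):
        raise GeometryError("alkylation flags must match residue count")
    phi = np.array([t[0] for t in torsions], float)
    psi = np.array([t[1] for t in torsions], float)
    omega = np.array([t[2] for t in torsions], float)
    arrs = build_backbone_arrays(phi, psi, omega)
    chain = []
    for i, alk in enumerate(alkylated):
        chain.append(
            BackboneResidueCoords(
                n=arrs["N"][i],
                ca=arrs["CA"][i],
                c=arrs["C"][i],
                o=arrs["O"][i],
                h=None if alk else arrs["H"][i],
                cm=arrs["CM"][i] if alk else None,
                phi=phi[i],
                psi=psi[i],
                omega=omega[i],
            )
        )
    return chain


def measure_torsions(
    chain: Sequence[BackboneResidueCoords],
    topology: Literal["open", "cyclic"] = "open",
) -> np.ndarray:
    """Measure (phi, psi, omega) per residue from coordinates.

    Returns an (L, 3) array; entries undefined for an open chain (phi and
    omega of residue 1, psi of the last residue) are NaN.
    """
    L = len(chain)
    out = np.full((L, 3), math.nan)
    for i in range(L):
        prev_ok = topology == "cyclic" or i > 0
        next_ok = topology == "cyclic" or i < L - 1
        prev = chain[(i - 1) % L]
        nxt = chain[(i + 1) % L]
        r = chain[i]
        if prev_ok:
            out[i, 0] = dihedral(prev.c, r.n, r.ca, r.c)
            out[i, 2] = dihedral(prev.ca, prev.c, r.n, r.ca)
        if next_ok:
            out[i, 1] = dihedral(r.n, r.ca, r.c, nxt.n)
    return out


def replace_amide_hydrogens(chain: list[BackboneResidueCoords], topology: Literal["open", "cyclic"] = "cyclic") -> None:
    """Re-place amide hydrogens (and N-methyl carbons) in the plane defined
    by the actual preceding carbonyl carbon.  Used after ring fusion, where
    residue 1 gains a real predecessor.  Mutates the chain in place."""
    L = len(chain)
    for i, r in enumerate(chain):
        if topology == "open" and i == 0:
            continue
        c_prev = chain[(i - 1) % L].c
        if r.cm is not None:
            r.cm = _amide_substituent(c_prev, r.n, r.ca, _G["N-CH3"])
        else:
            r.h = _amide_substituent(c_prev, r.n, r.ca, _G["N-H"])


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns the transform ``T`` minimising ``|T(mobile) - target|`` and the
    attained RMSD in angstroms.
    """
    mob = np.asarray(mobile, float)
    tgt = np.asarray(target, float)
    if mob.shape != tgt.shape:
        raise GeometryError("size mismatch")
    if mob.ndim != 2 or mob.shape[1] != 3 or mob.shape[0] < 3:
        raise GeometryError("need at least 3 points of dimension 3")
    mc = mob.mean(axis=0)
    tc = tgt.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt - tc, mob - mc)
    R = rot.as_matrix()
    t = tc - R @ mc
    # compute the rmsd from the residuals directly: the svd-based rssd
    # loses half the digits near zero
    resid = mob @ R.T + t - tgt
    rmsd = math.sqrt(float((resid * resid).sum()) / mob.shape[0])
    return RigidTransform(R, t), rmsd


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric backbone hydrogen-bond definition (beta-sheet-like).

    Defaults: H...O <= 2.5 A, N-H...O angle >= 135 deg, H...O=C angle >=
    90 deg, and donor/acceptor at least 2 residues apart in sequence.
    """

    max_ho_distance: float = 2.5
    min_nho_angle: float = 135.0
    min_hoc_angle: float = 90.0
    min_sequence_separation: int = 2

    def __post_init__(self) -> None:
        if self.max_ho_distance <= 0 or self.min_sequence_separation < 1:
            raise GeometryError("hydrogen-bond criteria must be positive")


@dataclass(frozen=True)
class HBond:
    donor: int
    acceptor: int
    ho_distance: float
    nho_angle: float
    hoc_angle: float


def find_clashes(
    chain: Sequence[BackboneResidueCoords],
    radius: float = 2.8,
    topology: Literal["open", "cyclic"] = "open",
    criteria: HBondCriteria | None = None,
) -> list[tuple[int, int]]:
    """Residue pairs with heavy atoms closer than ``radius``.

    Pairs of residues adjacent in sequence (wrapping for cyclic topology)
    are skipped — their atoms share short covalent paths.  When
    ``criteria`` is given, the donor-nitrogen / acceptor-carbonyl contacts
    of detected hydrogen bonds are exempt: a bonded N...O pair sits near
    2.9 A by design and is not a clash.
    """
    L = len(chain)
    exempt: set[tuple[int, int, int, int]] = set()
    if criteria is not None:
        # atom indices within heavy_atoms(): 0=N, 2=C, 3=O
        for b in detect_hbonds(chain, criteria, topology):
            exempt.add((b.donor, 0, b.acceptor, 3))
            exempt.add((b.donor, 0, b.acceptor, 2))
    clashes: list[tuple[int, int]] = []
    for i in range(L):
        ai = chain[i].heavy_atoms()
        for j in range(i + 1, L):
            sep = j - i
            if topology == "cyclic":
                sep = min(sep, L - sep)
            if sep < 2:
                continue
            aj = chain[j].heavy_atoms()
            hit = False
            for ia, a in enumerate(ai):
                for ja, b in enumerate(aj):
                    if (i, ia, j, ja) in exempt or (j, ja, i, ia) in exempt:
                        continue
                    if float(np.linalg.norm(a - b)) < radius:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                clashes.append((i, j))
    return clashes


def detect_hbonds(
    chain: Sequence[BackboneResidueCoords],
    criteria: HBondCriteria = HBondCriteria(),
    topology: Literal["open", "cyclic"] = "open",
) -> list[HBond]:
    """All backbone-backbone hydrogen bonds meeting the criteria.

    Tertiary (N-alkylated, incl. proline) nitrogens never donate.  For a
    cyclic chain, sequence separation wraps around the ring closure.
    """
    L = len(chain)
    bonds: list[HBond] = []
    for i, don in enumerate(chain):
        if don.h is None:
            continue
        for j, acc in enumerate(chain):
            sep = abs(i - j)
            if topology == "cyclic":
                sep = min(sep, L - sep)
            if sep < criteria.min_sequence_separation:
                continue
            d = float(np.linalg.norm(don.h - acc.o))
            if d > criteria.max_ho_distance:
                continue
            a_nho = float(angle_deg(don.n, don.h, acc.o))
            if a_nho < criteria.min_nho_angle:
                continue
            a_hoc = float(angle_deg(don.h, acc.o, acc.c))
            if a_hoc < criteria.min_hoc_angle:
                continue
            bonds.append(HBond(i, j, d, a_nho, a_hoc))
    return bonds
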