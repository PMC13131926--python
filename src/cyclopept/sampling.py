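"""Sampling of hydrogen-bonded open loops G-(NMe-G)n-G.

Loops are built from glycine/sarcosine torsion space: two terminal glycines
(secondary amides, hydrogen-bond donors) separated by ``n`` N-methylglycines
(n = 3, 4 or 5).  A candidate torsion draw is accepted only when the two
terminal residues form a beta-strand-like backbone hydrogen bond, which is
what later allows pairs of loops to fuse into fully hydrogen-bond-satisfied
macrocycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BackboneResidueCoords,
    HBond,
    HBondCriteria,
    RigidTransform,
    build_backbone_arrays,
    detect_hbonds,
    find_clashes,
    frame_transform,
)

__all__ = [
    "RamaRegion",
    "RamachandranModel",
    "Loop",
    "LoopLibrary",
    "sample_loop",
    "generate_library",
    "SamplingError",
]

SUPPORTED_LENGTHS = (3, 4, 5)


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class RamaRegion:
    """Rectangular phi/psi basin with a sampling weight."""

    name: str
    phi_center: float
    phi_half_width: float
    psi_center: float
    psi_half_width: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        for c, h in ((self.phi_center, self.phi_half_width), (self.psi_center, self.psi_half_width)):
            if abs(c) + h > 180.0 + 1e-9:
                raise SamplingError(f"region {self.name} extends outside [-180, 180]")
        if self.weight < 0:
            raise SamplingError("region weight must be non-negative")


@dataclass(frozen=True)
class RamachandranModel:
    """Torsion-sampling model for achiral glycine/sarcosine residues.

    The four default basins cover both negative- and positive-phi halves of
    the map (glycine and sarcosine are achiral, so the map is symmetric).
    ``cis_probability`` applies only to tertiary (N-alkylated) amides, which
    unlike secondary amides populate the cis isomer appreciably.
    """

    regions: tuple[RamaRegion, ...] = (
        RamaRegion("alphaR", -95.0, 35.0, -40.0, 30.0, 1.0),
        RamaRegion("alphaL", 95.0, 35.0, 40.0, 30.0, 1.0),
        RamaRegion("betaExt", -130.0, 40.0, 135.0, 45.0, 1.0),
        RamaRegion("betaExtMirror", 130.0, 40.0, -135.0, 45.0, 1.0),
    )
    cis_probability: float = 0.1
    omega_jitter_deg: float = 5.0

    def __post_init__(self) -> None:
        if not self.regions:
            raise SamplingError("need at least one Ramachandran region")
        if not (0.0 <= self.cis_probability <= 1.0):
            raise SamplingError("cis probability must be in [0, 1]")
        total = sum(r.weight for r in self.regions)
        if total <= 0:
            raise SamplingError("region weights must sum to a positive value")

    def weights(self) -> np.ndarray:
        w = np.array([r.weight for r in self.regions], float)
        return w / w.sum()

    def sample_phi_psi(self, rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
        idx = rng.choice(len(self.regions), size=size, p=self.weights())
        lo_phi = np.array([r.phi_center - r.phi_half_width for r in self.regions])
        hi_phi = np.array([r.phi_center + r.phi_half_width for r in self.regions])
        lo_psi = np.array([r.psi_center - r.psi_half_width for r in self.regions])
        hi_psi = np.array([r.psi_center + r.psi_half_width for r in self.regions])
        u = rng.uniform(size=size)
        v = rng.uniform(size=size)
        phi = lo_phi[idx] + u * (hi_phi[idx] - lo_phi[idx])
        psi = lo_psi[idx] + v * (hi_psi[idx] - lo_psi[idx])
        return phi, psi


@dataclass
class Loop:
    """An accepted open loop with its terminal hydrogen bond and the rigid
    transforms between its terminal NCaC frames (both senses)."""

    loop_id: str
    n_internal: int
    residues: list[BackboneResidueCoords]
    terminal_hbond: HBond
    forward_transform: RigidTransform
    reverse_transform: RigidTransform
    torsions: np.ndarray  # (L, 3) phi/psi/omega as sampled
    draws_used: int = 1

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def alkylation(self) -> list[bool]:
        return [r.n_alkylated for r in self.residues]


@dataclass
class LoopLibrary:
    loops: list[Loop]
    acceptance_rate: dict[int, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


def _loop_rng(seed: int, n_internal: int, slot: int) -> np.random.Generator:
    # per-slot substream: libraries are order-independent and parallelisable
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(n_internal), int(slot)]))


def _terminal_hbonds(chain: list[BackboneResidueCoords], criteria: HBondCriteria) -> list[HBond]:
    """The terminal hydrogen bond, donated by the C-terminal glycine to the
    N-terminal glycine's carbonyl.

    Only this donor direction survives ring fusion: the N-terminal amide
    hydrogen is re-placed against the partner loop's last residue when the
    ring closes, and lands where the partner's C-terminal hydrogen sat.
    Each loop therefore contributes its C-to-N bond to the fused ring, and
    two such loops produce the ring's reciprocal (beta-pair-like) junction.
    """
    bonds = detect_hbonds(chain, criteria, topology="open")
    last = len(chain) - 1
    return [b for b in bonds if b.donor == last and b.acceptor == 0]


def _internally_clashed(chain: list[BackboneResidueCoords], radius: float, criteria: HBondCriteria) -> bool:
    """Whether any non-adjacent residues collide (hydrogen-bonded contacts
    exempt).  Self-overlapping conformers can never close into clash-free
    rings, so they are rejected at the source."""
    return bool(find_clashes(chain, radius, topology="open", criteria=criteria))


def _candidate_batch(
    n_internal: int,
    rama: RamachandranModel,
    rng: np.random.Generator,
    batch: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = n_internal + 2
    phi, psi = rama.sample_phi_psi(rng, batch * L)
    phi = phi.reshape(batch, L)
    psi = psi.reshape(batch, L)
    omega = np.full((batch, L), 180.0)
    # tertiary amides (internal residues 2..n+1) may be cis; the amide into
    # the C-terminal glycine and the anchor amide of residue 1 stay trans
    cis = rng.uniform(size=(batch, L)) < rama.cis_probability
    cis[:, 0] = False
    cis[:, -1] = False
    omega[cis] = 0.0
    jitter = rng.normal(scale=rama.omega_jitter_deg, size=(batch, L))
    omega = omega + np.clip(jitter, -15.0, 15.0)
    omega[:, 0] = 180.0  # residue-1 anchor amide: fixed trans, not a ring torsion
    omega = ((omega + 180.0) % 360.0) - 180.0
    return phi, psi, omega


def _angle_batch(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    u = a - b
    v = c - b
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return np.degrees(np.arccos(np.clip((u * v).sum(axis=-1), -1.0, 1.0)))


def _heavy_atom_batch(arrs: dict, alkylated: list[bool]) -> np.ndarray:
    """(B, A, 3) stack of heavy atoms: N, CA, C, O per residue plus CM for
    alkylated ones, in residue order."""
    cols = []
    for i, alk in enumerate(alkylated):
        for a in ("N", "CA", "C", "O"):
            cols.append(arrs[a][:, i])
        if alk:
            cols.append(arrs["CM"][:, i])
    return np.stack(cols, axis=1)


def _clash_pair_indices(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs into the heavy-atom stack for the self-clash screen:
    all atom pairs from residues >= 2 apart, minus the terminal hydrogen
    bond's donor-N / acceptor-O and donor-N / acceptor-C contacts."""
    alkylated = [False] + [True] * (L - 2) + [False]
    owner = []
    labels = []
    for i, alk in enumerate(alkylated):
        for a in ("N", "CA", "C", "O"):
            owner.append(i)
            labels.append(a)
        if alk:
            owner.append(i)
            labels.append("CM")
    A = len(owner)
    exempt = {("N", L - 1, "O", 0), ("N", L - 1, "C", 0)}
    ii, jj = [], []
    for x in range(A):
        for y in range(x + 1, A):
            if abs(owner[x] - owner[y]) < 2:
                continue
            key = (labels[x], owner[x], labels[y], owner[y])
            if key in exempt or (key[2], key[3], key[0], key[1]) in exempt:
                continue
            ii.append(x)
            jj.append(y)
    return np.array(ii), np.array(jj)


def _chain_from_arrays(arrs: dict, phi, psi, omega, alkylated) -> list[BackboneResidueCoords]:
    chain = []
    for i, alk in enumerate(alkylated):
        chain.append(
            BackboneResidueCoords(
                n=arrs["N"][i].copy(),
                ca=arrs["CA"][i].copy(),
                c=arrs["C"][i].copy(),
                o=arrs["O"][i].copy(),
                h=None if alk else arrs["H"][i].copy(),
                cm=arrs["CM"][i].copy() if alk else None,
                phi=float(phi[i]),
                psi=float(psi[i]),
                omega=float(omega[i]),
            )
        )
    return chain


def sample_loop(
    n_internal: int,
    rama: RamachandranModel = RamachandranModel(),
    seed: int = 0,
    criteria: HBondCriteria = HBondCriteria(),
    max_draws: int = 200_000,
    slot: int = 0,
    batch: int = 1024,
    clash_radius: float = 2.8,
) -> Loop:
    """Rejection-sample one hydrogen-bonded, internally clash-free loop.

    Draws torsion sets until the C-terminal glycine donates a backbone
    hydrogen bond to the N-terminal glycine's carbonyl and no two
    non-adjacent residues collide, or ``max_draws`` candidates have been
    tried.  Identical (seed, slot) always reproduces the same loop.
    """
    if n_internal not in SUPPORTED_LENGTHS:
        raise SamplingError(f"unsupported loop length: n_internal={n_internal} (expected 3, 4 or 5)")
    rng = _loop_rng(seed, n_internal, slot)
    L = n_internal + 2
    alkylated = [False] + [True] * n_internal + [False]
    pair_i, pair_j = _clash_pair_indices(L)
    draws = 0
    while draws < max_draws:
        nb = min(batch, max_draws - draws)
        phi, psi, omega = _candidate_batch(n_internal, rama, rng, nb)
        arrs = build_backbone_arrays(phi, psi, omega)
        # vectorised screen: terminal H-bond geometry, then steric self-check
        H, O, N, C = arrs["H"], arrs["O"], arrs["N"], arrs["C"]
        d_rev = np.linalg.norm(H[:, -1] - O[:, 0], axis=-1)
        cand = np.flatnonzero(d_rev <= criteria.max_ho_distance)
        if cand.size:
            nho = _angle_batch(N[cand, -1], H[cand, -1], O[cand, 0])
            hoc = _angle_batch(H[cand, -1], O[cand, 0], C[cand, 0])
            cand = cand[(nho >= criteria.min_nho_angle) & (hoc >= criteria.min_hoc_angle)]
        if cand.size:
            sub = {a: arrs[a][cand] for a in arrs}
            heavy = _heavy_atom_batch(sub, alkylated)
            d2 = ((heavy[:, pair_i] - heavy[:, pair_j]) ** 2).sum(axis=-1)
            cand = cand[~(d2 < clash_radius**2).any(axis=1)]
        for k in cand:
            chain = _chain_from_arrays(
                {a: arrs[a][k] for a in arrs}, phi[k], psi[k], omega[k], alkylated
            )
            bonds = _terminal_hbonds(chain, criteria)
            if len(bonds) != 1 or _internally_clashed(chain, clash_radius, criteria):
                continue
            fwd = frame_transform(chain[0].frame(), chain[-1].frame())
            return Loop(
                loop_id=f"n{n_internal}_{slot:05d}",
                n_internal=n_internal,
                residues=chain,
                terminal_hbond=bonds[0],
                forward_transform=fwd,
                reverse_transform=fwd.inverse(),
                torsions=np.column_stack([phi[k], psi[k], omega[k]]),
                draws_used=draws + int(k) + 1,
            )
        draws += nb
    raise SamplingError(
        f"no hydrogen-bonded loop found for n={n_internal}, slot {slot} within {max_draws} draws"
    )


def generate_library(
    counts: dict[int, int],
    rama: RamachandranModel = RamachandranModel(),
    seed: int = 0,
    criteria: HBondCriteria = HBondCriteria(),
    max_draws: int = 200_000,
    clash_radius: float = 2.8,
) -> LoopLibrary:
    """Generate the requested number of accepted loops per internal length.

    ``counts`` maps n_internal (3, 4, 5) to the number of loops wanted.
    Acceptance rates (accepted / torsion draws) are recorded per length.
    """
    loops: list[Loop] = []
    rates: dict[int, float] = {}
    for n, count in sorted(counts.items()):
        if count < 0:
            raise SamplingError("loop counts must be non-negative")
        if count == 0:
            continue
        if n not in SUPPORTED_LENGTHS:
            raise SamplingError(f"unsupported loop length: n_internal={n}")
        total_draws = 0
        accepted = 0
        slot = 0
        while accepted < count:
            try:
                loop = sample_loop(n, rama, seed, criteria, max_draws, slot=slot, clash_radius=clash_radius)
            except SamplingError:
                # barren substream: charge the cap and move to the next slot
                total_draws += max_draws
                slot += 1
                if slot > 20 * count + 100:
                    raise
                continue
            loops.append(loop)
            total_draws += loop.draws_used
            accepted += 1
            slot += 1
        rates[n] = count / total_draws if total_draws else math.nan
    return LoopLibrary(loops=loops, acceptance_rate=rates)
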