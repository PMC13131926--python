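"""Transform hashing, closure search, fusion and C2 symmetrization."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cyclopept.closure import (
    BinWidths,
    ClosureError,
    c2_operator,
    close_ring_torsions,
    find_closures,
    fuse,
    index_library,
    symmetrize_c2,
    terminal_alignment,
    transform_key,
    transform_keys,
)
from cyclopept.geometry import RigidTransform, superpose
from cyclopept.model import Macrocycle
from cyclopept.sampling import sample_loop


def _transform(rotvec_deg, translation):
    return RigidTransform(
        Rotation.from_rotvec(np.asarray(rotvec_deg, float), degrees=True).as_matrix(),
        np.asarray(translation, float),
    )


class TestTransformKey:
    def test_identity_maps_to_origin_key(self):
        assert transform_key(RigidTransform.identity()) == (0, 0, 0, 0, 0, 0)

    def test_sub_bin_perturbation_keeps_key(self):
        t1 = _transform([40.0, 3.0, -20.0], [0.4, 0.4, 0.4])
        t2 = _transform([40.1, 3.0, -20.0], [0.41, 0.4, 0.4])
        bins = BinWidths(1.0, 15.0)
        assert transform_key(t1, bins) == transform_key(t2, bins)

    def test_translation_bin_edges_floor(self):
        t = _transform([0.0, 0.0, 1e-9], [1.6, 0.0, 0.0])
        key = transform_key(t, BinWidths(1.0, 15.0))
        assert key[0] == 1
        assert key[1] == key[2] == 0

    def test_nonpositive_widths_rejected(self):
        with pytest.raises(ClosureError, match="invalid binning"):
            BinWidths(0.0, 15.0)

    def test_near_involution_gets_antipodal_alias(self):
        t = _transform([178.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        keys = transform_keys(t, BinWidths(1.0, 15.0))
        assert len(keys) == 2
        # the alias is the (theta - 360) representation of the same rotation
        assert keys[1][3] < 0 < keys[0][3]


class TestIndexAndClosures:
    def test_every_loop_contributes_both_senses(self, small_library):
        table = index_library(small_library.loops)
        assert table.n_entries() == 2 * len(small_library.loops)
        fwd_ids = {i for ids in table.forward.values() for i in ids}
        rev_ids = {i for ids in table.reverse.values() for i in ids}
        assert fwd_ids == rev_ids == set(table.loops)

    def test_id_collision_rejected(self, small_library):
        loops = list(small_library.loops)
        with pytest.raises(ClosureError, match="id collision"):
            index_library(loops + [loops[0]])

    def test_empty_library_rejected(self):
        with pytest.raises(ClosureError, match="empty library"):
            index_library([])

    @pytest.mark.parametrize("neighbor_bins", [False, True])
    def test_closures_match_quadratic_scan_oracle(self, small_library, neighbor_bins):
        """Hash retrieval must equal a brute-force all-pairs binned
        comparison (exact set equality of unordered id pairs)."""
        loops = small_library.loops
        bins = BinWidths()
        table = index_library(loops, bins)
        got = {tuple(sorted((p.loop_i, p.loop_j))) for p in find_closures(table, neighbor_bins)}

        def keys_near(keys):
            if not neighbor_bins:
                return set(keys)
            out = set()
            for k in keys:
                for d in itertools.product((-1, 0, 1), repeat=6):
                    out.add(tuple(x + y for x, y in zip(k, d)))
            return out

        expected = set()
        for a in loops:
            for b in loops:
                fwd = keys_near(transform_keys(a.forward_transform, bins))
                rev = set(transform_keys(b.reverse_transform, bins))
                if fwd & rev:
                    expected.add(tuple(sorted((a.loop_id, b.loop_id))))
        assert got == expected

    def test_distinct_keys_give_no_pairs(self, small_library):
        # spread loops apart so every key is unique
        loops = []
        for k, lp in enumerate(small_library.loops[:5]):
            shifted = RigidTransform(lp.forward_transform.rotation,
                                     lp.forward_transform.translation + 100.0 * (k + 1))
            lp2 = type(lp)(
                loop_id=lp.loop_id, n_internal=lp.n_internal, residues=lp.residues,
                terminal_hbond=lp.terminal_hbond, forward_transform=shifted,
                reverse_transform=shifted.inverse(), torsions=lp.torsions,
            )
            loops.append(lp2)
        assert find_closures(index_library(loops)) == []


class TestFusion:
    def test_self_fusion_of_5_residue_loop_gives_8_ring(self, mc1_ring):
        assert len(mc1_ring) == 8
        # a closed 8-ring has exactly 8 backbone amide (C-N) bonds
        bonds = [
            float(np.linalg.norm(mc1_ring.coords[i].c - mc1_ring.coords[(i + 1) % 8].n))
            for i in range(8)
        ]
        assert len(bonds) == 8
        assert all(abs(b - 1.329) <= 0.1 for b in bonds)

    def test_5_plus_6_fusion_gives_9_ring(self):
        a = sample_loop(3, seed=11, slot=25)
        b = sample_loop(4, seed=11, slot=20)
        mc = fuse(a, b)
        assert len(mc) == len(a) + len(b) - 2 == 9

    def test_fused_ring_has_exactly_two_transannular_bonds(self, mc1_ring):
        assert len(mc1_ring.transannular_hbonds) == 2
        donors = sorted((b.donor, b.acceptor) for b in mc1_ring.transannular_hbonds)
        # reciprocal pair across the two junction residues
        assert donors == [(0, 4), (4, 0)]

    def test_terminal_rmsd_gate(self):
        a = sample_loop(3, seed=11, slot=0)
        b = sample_loop(5, seed=11, slot=1)
        _, rmsd = terminal_alignment(a, b)
        if rmsd > 0.5:
            with pytest.raises(ClosureError, match="closure failure"):
                fuse(a, b)

    def test_ccd_closes_ring_torsions(self, mc1_ring):
        import numpy as np
        from cyclopept.geometry import measure_torsions

        tor = measure_torsions(mc1_ring.coords, "cyclic")
        closed, gap, sweeps = close_ring_torsions(tor)
        assert gap < 0.03
        assert closed.shape == tor.shape


class TestSymmetrize:
    def test_exactly_invariant_under_projected_operator(self, mc1_ring):
        S = c2_operator(mc1_ring)
        # S is an exact involution
        assert np.allclose(S.compose(S).rotation, np.eye(3), atol=1e-12)
        assert np.allclose(S.compose(S).translation, 0.0, atol=1e-9)
        # ring maps onto itself under the half-turn permutation + S
        L = len(mc1_ring)
        atoms = np.array([[r.n, r.ca, r.c, r.o] for r in mc1_ring.coords]).reshape(-1, 3)
        perm = np.array([[mc1_ring.coords[(i + L // 2) % L].n,
                          mc1_ring.coords[(i + L // 2) % L].ca,
                          mc1_ring.coords[(i + L // 2) % L].c,
                          mc1_ring.coords[(i + L // 2) % L].o] for i in range(L)]).reshape(-1, 3)
        assert np.abs(S.apply(perm) - atoms).max() < 1e-9

    def test_idempotent(self, mc1_ring):
        once = np.array([[r.n, r.ca, r.c, r.o] for r in mc1_ring.coords])
        twice = np.array([[r.n, r.ca, r.c, r.o] for r in symmetrize_c2(mc1_ring).coords])
        assert np.abs(once - twice).max() < 1e-9

    def test_noise_split_evenly_between_halves(self, mc1_ring, rng):
        noisy = Macrocycle(
            residues=list(mc1_ring.residues),
            coords=[r.copy() for r in mc1_ring.coords],
        )
        # perturb every atom of one half by a random 0.1 A displacement
        for r in noisy.coords[: len(noisy) // 2]:
            for at in ("n", "ca", "c", "o", "h", "cm"):
                v = getattr(r, at)
                if v is None:
                    continue
                d = rng.normal(size=3)
                setattr(r, at, v + 0.1 * d / np.linalg.norm(d))
        sym = symmetrize_c2(noisy)
        moved = [
            float(np.linalg.norm(a.ca - b.ca)) for a, b in zip(sym.coords, noisy.coords)
        ]
        # averaging splits the perturbation: each atom moves about half of it
        assert all(0.02 < m < 0.09 for m in moved)
        S = c2_operator(sym)
        L = len(sym)
        atoms = np.array([[r.ca] for r in sym.coords]).reshape(-1, 3)
        perm = np.array([[sym.coords[(i + L // 2) % L].ca] for i in range(L)]).reshape(-1, 3)
        assert np.abs(S.apply(perm) - atoms).max() < 1e-9

    def test_odd_ring_rejected(self):
        a = sample_loop(3, seed=11, slot=25)
        b = sample_loop(4, seed=11, slot=20)
        mc = fuse(a, b)  # 9-ring
        with pytest.raises(ClosureError, match="not C2-compatible"):
            symmetrize_c2(mc)
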