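"""Geometry core: torsion-driven building, frames, superposition and
hydrogen-bond detection."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cyclopept.geometry import (
    IDEAL_GEOMETRY,
    BackboneResidueCoords,
    GeometryError,
    HBondCriteria,
    ResidueFrame,
    RigidTransform,
    build_backbone,
    detect_hbonds,
    dihedral,
    frame_transform,
    measure_torsions,
    superpose,
)


def random_frame(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return ResidueFrame(rng.normal(scale=5.0, size=3), R)


class TestBuildBackbone:
    def test_single_residue_canonical_placement(self):
        chain = build_backbone([(60.0, -45.0, 180.0)])
        assert len(chain) == 1
        # residue 1 is anchored at the origin frame: N at the origin is not
        # required, but bond geometry must be ideal
        assert np.linalg.norm(chain[0].ca - chain[0].n) == pytest.approx(IDEAL_GEOMETRY["N-CA"], abs=1e-9)
        assert np.linalg.norm(chain[0].c - chain[0].ca) == pytest.approx(IDEAL_GEOMETRY["CA-C"], abs=1e-9)

    def test_trans_dipeptide_ca_ca_distance_matches_planar_oracle(self):
        """For an all-trans (planar zig-zag) peptide the CA-CA distance
        follows from 2D turtle geometry through C and N."""
        chain = build_backbone([(180.0, 180.0, 180.0)] * 2)
        built = float(np.linalg.norm(chain[1].ca - chain[0].ca))
        # independent 2D computation: walk CA -> C -> N -> CA in the plane
        th1 = math.radians(180.0 - IDEAL_GEOMETRY["CA-C-N"])  # exterior turn at C
        th2 = math.radians(180.0 - IDEAL_GEOMETRY["C-N-CA"])  # exterior turn at N
        x = IDEAL_GEOMETRY["CA-C"] + IDEAL_GEOMETRY["C-N"] * math.cos(th1) + IDEAL_GEOMETRY["N-CA"] * math.cos(th1 - th2)
        y = IDEAL_GEOMETRY["C-N"] * math.sin(th1) + IDEAL_GEOMETRY["N-CA"] * math.sin(th1 - th2)
        expected = math.hypot(x, y)
        assert built == pytest.approx(expected, abs=1e-9)
        assert built == pytest.approx(3.80, abs=0.01)

    def test_measure_roundtrip_closes_to_1e6_degrees(self, rng):
        n = 7
        tors = np.column_stack(
            [rng.uniform(-170, 170, n), rng.uniform(-170, 170, n), rng.uniform(-170, 170, n)]
        )
        alk = [False, True, False, True, True, False, False]
        chain = build_backbone([tuple(t) for t in tors], alk)
        measured = measure_torsions(chain, "open")
        defined = np.isfinite(measured)
        delta = np.abs(((measured - tors + 180.0) % 360.0) - 180.0)
        assert np.all(delta[defined] < 1e-6)

    def test_rebuild_from_measured_torsions_reproduces_coordinates(self, rng):
        n = 6
        tors = np.column_stack(
            [rng.uniform(-170, 170, n), rng.uniform(-170, 170, n), rng.uniform(-170, 170, n)]
        )
        chain = build_backbone([tuple(t) for t in tors])
        measured = measure_torsions(chain, "open")
        # undefined entries (phi/omega of residue 1, psi of the last) are
        # not recoverable from an open chain; keep the originals there
        filled = np.where(np.isfinite(measured), measured, tors)
        rebuilt = build_backbone([tuple(t) for t in filled])
        a = np.array([[r.n, r.ca, r.c, r.o] for r in chain]).reshape(-1, 3)
        b = np.array([[r.n, r.ca, r.c, r.o] for r in rebuilt]).reshape(-1, 3)
        t, rmsd = superpose(b, a)
        assert rmsd < 1e-6

    def test_empty_chain_rejected(self):
        with pytest.raises(GeometryError, match="empty chain"):
            build_backbone([])

    def test_out_of_range_torsion_rejected(self):
        with pytest.raises(GeometryError, match="invalid torsion"):
            build_backbone([(200.0, 0.0, 180.0)])

    def test_exactly_one_amide_substituent(self):
        chain = build_backbone([(-60, -45, 180)] * 3, [False, True, False])
        for r, alk in zip(chain, [False, True, False]):
            assert (r.h is None) == alk
            assert (r.cm is not None) == alk


class TestRigidTransformAlgebra:
    def test_identity_and_inverse(self, rng):
        a = random_frame(rng)
        t = frame_transform(a, a)
        assert t.isclose(RigidTransform.identity(), atol=1e-9)
        b = random_frame(rng)
        ab = frame_transform(a, b)
        ba = frame_transform(b, a)
        assert ab.compose(ba).isclose(RigidTransform.identity(), atol=1e-9)

    def test_push_reproduces_target_frame(self, rng):
        a, b = random_frame(rng), random_frame(rng)
        t = frame_transform(a, b)
        b2 = a.push(t)
        assert np.allclose(b2.origin, b.origin, atol=1e-9)
        assert np.allclose(b2.axes, b.axes, atol=1e-9)

    def test_pure_translation_expressed_in_local_axes(self, rng):
        a = random_frame(rng)
        shift = np.array([1.0, 2.0, 3.0])
        b = ResidueFrame(a.origin + shift, a.axes.copy())
        t = frame_transform(a, b)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, a.axes.T @ shift, atol=1e-12)

    def test_transform_composition_chains(self, rng):
        a, b, c = (random_frame(rng) for _ in range(3))
        direct = frame_transform(a, c)
        chained = frame_transform(a, b).compose(frame_transform(b, c))
        assert direct.isclose(chained, atol=1e-8)

    def test_degenerate_frame_rejected(self):
        with pytest.raises(GeometryError, match="degenerate frame"):
            ResidueFrame.from_backbone([0, 0, 0], [1, 0, 0], [2, 0, 0])

    def test_improper_rotation_rejected(self):
        with pytest.raises(GeometryError, match="improper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestSuperpose:
    def test_identical_and_rigidly_moved_sets_give_zero(self, rng):
        pts = rng.normal(size=(6, 3))
        _, r0 = superpose(pts, pts)
        assert r0 == pytest.approx(0.0, abs=1e-12)
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        moved = pts @ R.T + np.array([3.0, -1.0, 2.0])
        t, r1 = superpose(moved, pts)
        assert r1 < 1e-9
        assert np.allclose(t.apply(moved), pts, atol=1e-9)

    def test_matches_rotation_search_oracle_on_toy_sets(self, rng):
        """Kabsch result equals a brute-force rotation search (coarse
        quaternion grid + local refinement), to 1e-6."""
        mobile = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.3, 0.4, 1.8]])
        target = np.array([[0.1, 0, 0], [1.4, 0.2, 0], [-0.2, 1.9, 0.1], [0.5, 0.2, 1.7]])
        t, rmsd = superpose(mobile, target)

        mc = mobile - mobile.mean(axis=0)
        tc = target - target.mean(axis=0)

        def cost(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return float(np.sqrt((((mc @ R.T) - tc) ** 2).sum(axis=1).mean()))

        grid = Rotation.random(3000, random_state=np.random.RandomState(0)).as_rotvec()
        best = min(grid, key=cost)
        refined = minimize(cost, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
        assert rmsd == pytest.approx(refined.fun, abs=1e-6)

    def test_rmsd_invariant_under_prerotation(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        _, r1 = superpose(a, b)
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        _, r2 = superpose(a @ R.T + 5.0, b)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_size_mismatch_rejected(self):
        with pytest.raises(GeometryError, match="size mismatch"):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def _fake_residue(n, h, ca, c, o, alkylated=False):
    return BackboneResidueCoords(
        n=np.array(n, float), ca=np.array(ca, float), c=np.array(c, float),
        o=np.array(o, float),
        h=None if alkylated else np.array(h, float),
        cm=np.array(h, float) if alkylated else None,
    )


def _textbook_pair(alkylated_donor=False):
    """Two residues in ideal reciprocal (antiparallel beta-pair-like)
    hydrogen-bond geometry, separated in sequence by two remote spacers.

    Both N-H...O contacts are collinear (angle 180 deg) with H...O =
    1.89 A, and each carbonyl makes an H...O=C angle of ~122 deg.
    """
    # donor A: N-H along +x toward B's carbonyl O at (2.9, 0, 0)
    a = _fake_residue(
        n=[0.0, 0.0, 0.0], h=[1.01, 0.0, 0.0], ca=[-0.8, -1.1, 0.0],
        c=[1.2, -2.2, 0.0], o=[1.9, -3.3, 0.0], alkylated=alkylated_donor,
    )
    # donor B: N-H along -x toward A's carbonyl O at (1.9, -3.3, 0)
    b = _fake_residue(
        n=[4.8, -3.3, 0.0], h=[3.79, -3.3, 0.0], ca=[5.6, -2.2, 0.0],
        c=[3.6, 1.1, 0.0], o=[2.9, 0.0, 0.0],
    )
    spacer1 = _fake_residue(n=[0, 5, 50], h=[0, 6, 50], ca=[1, 5, 50], c=[2, 5, 50], o=[2, 6, 50], alkylated=True)
    spacer2 = _fake_residue(n=[5, 5, 50], h=[5, 6, 50], ca=[6, 5, 50], c=[7, 5, 50], o=[7, 6, 50], alkylated=True)
    return [a, spacer1, spacer2, b]


class TestDetectHbonds:
    def test_ideal_reciprocal_pair_gives_two_bonds(self):
        chain = _textbook_pair()
        bonds = detect_hbonds(chain, HBondCriteria(), "open")
        pairs = {(b.donor, b.acceptor) for b in bonds}
        assert (0, 3) in pairs and (3, 0) in pairs
        assert len(bonds) == 2
        for b in bonds:
            assert b.ho_distance <= 2.5
            assert b.nho_angle >= 135.0

    def test_nmethylated_donor_cannot_donate(self):
        chain = _textbook_pair(alkylated_donor=True)
        pairs = {(b.donor, b.acceptor) for b in detect_hbonds(chain, HBondCriteria(), "open")}
        assert (0, 3) not in pairs
        assert (3, 0) in pairs

    def test_distant_atoms_give_empty_list(self):
        chain = _textbook_pair()
        far = [r.moved_by(RigidTransform(np.eye(3), np.array([50.0 * i, 0, 0]))) for i, r in enumerate(chain)]
        assert detect_hbonds(far, HBondCriteria(), "open") == []

    def test_adjacent_residues_never_bond(self):
        chain = _textbook_pair()
        bonds = detect_hbonds(chain, HBondCriteria(min_sequence_separation=2), "open")
        assert all(abs(b.donor - b.acceptor) >= 2 for b in bonds)

    def test_output_invariant_under_rigid_motion(self, rng):
        chain = _textbook_pair()
        R = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        t = RigidTransform(R, np.array([4.0, -2.0, 9.0]))
        moved = [r.moved_by(t) for r in chain]
        b1 = detect_hbonds(chain, HBondCriteria(), "open")
        b2 = detect_hbonds(moved, HBondCriteria(), "open")
        assert [(b.donor, b.acceptor) for b in b1] == [(b.donor, b.acceptor) for b in b2]
        for x, y in zip(b1, b2):
            assert x.ho_distance == pytest.approx(y.ho_distance, abs=1e-9)


def test_dihedral_sign_convention_matches_reference():
    """Spot-check the IUPAC sign against an independently computed case."""
    p = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.5, 0], [1.0, 1.5, 1.0]])
    # by construction: looking down the 1->2 axis, atom 3 is rotated
    # counterclockwise from atom 0 => negative dihedral near -45 deg
    val = float(dihedral(*p))
    assert val == pytest.approx(-45.0, abs=1e-9)
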