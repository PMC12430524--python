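"""Torsion computation, chain building round trips, Kabsch superposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import angleforest as af
from angleforest.circular import wrap_difference
from angleforest.geometry import kabsch_rmsd, torsion_angle


def projection_oracle_torsion(p1, p2, p3, p4):
    """Independent torsion formula: project the outer bonds onto the plane
    normal to the central bond and measure the signed angle between them."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b2 = p3 - p2
    b2 /= np.linalg.norm(b2)
    u = (p1 - p2) - np.dot(p1 - p2, b2) * b2
    v = (p4 - p3) - np.dot(p4 - p3, b2) * b2
    x = np.dot(u, v)
    y = np.dot(np.cross(u, v), b2)
    return np.rad2deg(np.arctan2(y, x))


class TestTorsionAngle:
    def test_planar_cis_is_zero(self):
        assert torsion_angle((1, 1, 0), (0, 0, 0), (1, 0, 0), (2, 1, 0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert abs(torsion_angle((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))) \
            == pytest.approx(180.0, abs=1e-12)

    def test_agrees_with_projection_oracle(self, rng):
        pts = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]
        assert torsion_angle(*pts) == pytest.approx(
            projection_oracle_torsion(*pts), abs=1e-9)
        for _ in range(50):
            q = rng.normal(size=(4, 3))
            try:
                ours = torsion_angle(*q)
            except ValueError:
                continue
            assert abs(wrap_difference(ours, projection_oracle_torsion(*q))) \
                < 1e-9

    def test_rigid_motion_invariance(self, rng):
        q = rng.normal(size=(4, 3))
        ref = torsion_angle(*q)
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(size=3) * 10
            moved = q @ R.T + t
            assert abs(wrap_difference(torsion_angle(*moved), ref)) < 1e-9

    def test_point_reversal_preserves_and_mirror_negates(self, rng):
        # classic identities: torsion(DCBA) = torsion(ABCD);
        # a mirror image flips the sign
        q = rng.normal(size=(4, 3))
        fwd = torsion_angle(*q)
        rev = torsion_angle(*q[::-1])
        assert abs(wrap_difference(rev, fwd)) < 1e-9
        mirrored = q * np.array([1.0, 1.0, -1.0])
        assert abs(wrap_difference(torsion_angle(*mirrored), -fwd)) < 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            torsion_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBuildExtractRoundTrip:
    def test_extended_chain_round_trip(self):
        phi = np.full(5, -180.0)
        psi = np.full(5, 180.0)
        coords = af.build_backbone_from_torsions(phi, psi)
        out = af.extract_phi_psi(coords)
        rec_phi = out[[c for c in out.columns if c.startswith("phi")]].to_numpy()[0]
        rec_psi = out[[c for c in out.columns if c.startswith("psi")]].to_numpy()[0]
        assert np.abs(wrap_difference(rec_phi, phi)).max() < 1e-6
        assert np.abs(wrap_difference(rec_psi, psi)).max() < 1e-6

    def test_four_residue_chain_has_six_torsions(self, rng):
        coords = af.build_backbone_from_torsions(
            rng.uniform(-179, 179, 3), rng.uniform(-179, 179, 3))
        assert coords.shape == (4, 3, 3)
        assert af.extract_phi_psi(coords).shape == (1, 6)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 25))
    def test_round_trip_identity_over_random_vectors(self, seed, n_res):
        r = np.random.default_rng(seed)
        phi = r.uniform(-179.5, 179.5, n_res - 1)
        psi = r.uniform(-179.5, 179.5, n_res - 1)
        coords = af.build_backbone_from_torsions(phi, psi)
        out = af.extract_phi_psi(coords).to_numpy()[0]
        recovered = np.concatenate([
            out[:n_res - 1], out[n_res - 1:]])
        target = np.concatenate([phi, psi])
        assert np.abs(wrap_difference(recovered, target)).max() < 1e-6

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            af.build_backbone_from_torsions([], [])

    def test_agrees_with_biotite_extraction(self, rng):
        import biotite.structure as struc

        phi = rng.uniform(-170, 170, 7)
        psi = rng.uniform(-170, 170, 7)
        coords = af.build_backbone_from_torsions(phi, psi)
        n_res = 8
        arr = struc.AtomArray(n_res * 3)
        arr.coord = coords.reshape(-1, 3)
        arr.chain_id = np.full(n_res * 3, "A")
        arr.res_id = np.repeat(np.arange(1, n_res + 1), 3)
        arr.res_name = np.full(n_res * 3, "GLY")
        arr.atom_name = np.tile(np.array(["N", "CA", "C"]), n_res)
        arr.element = np.tile(np.array(["N", "C", "C"]), n_res)
        bphi, bpsi, _ = struc.dihedral_backbone(arr)
        ours = af.extract_phi_psi(coords)
        assert np.allclose(
            ours.to_numpy()[0][:7],
            np.rad2deg(bphi[1:]), atol=1e-6)
        assert np.allclose(
            ours.to_numpy()[0][7:],
            np.rad2deg(bpsi[:-1]), atol=1e-6)


class TestKabsch:
    def test_self_superposition_is_zero(self, rng):
        X = rng.normal(size=(10, 3))
        R, rmsd = kabsch_rmsd(X, X)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_gives_zero_rmsd(self, rng):
        X = rng.normal(size=(25, 3))
        Rot = Rotation.random(rng=rng).as_matrix()
        Y = X @ Rot.T + rng.normal(size=3) * 5
        _, rmsd = kabsch_rmsd(X, Y)
        assert rmsd < 1e-9

    def test_symmetry_in_arguments(self, rng):
        X = rng.normal(size=(12, 3))
        Y = X + rng.normal(scale=0.3, size=(12, 3))
        assert kabsch_rmsd(X, Y)[1] == pytest.approx(kabsch_rmsd(Y, X)[1],
                                                     abs=1e-12)

    def test_matches_scipy_align_vectors(self, rng):
        X = rng.normal(size=(10, 3))
        Y = X.copy()
        Y[0] += np.array([1.0, 0.0, 0.0])
        _, ours = kabsch_rmsd(X, Y)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        _, rssd = Rotation.align_vectors(Yc, Xc)
        assert ours == pytest.approx(rssd / np.sqrt(len(X)), abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_rmsd(line, line)
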