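"""Distances, superposition, RMSD/RMSF, torsions, motif counting, OLS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cdrflex.geometry_metrics import (
    DegenerateGeometryError,
    classify_ss,
    count_ss_residues,
    dihedral,
    fit_linear,
    kabsch_superpose,
    pair_distance_series,
    phi_psi_series,
    rmsd,
    rmsd_series,
    rmsf_profile,
)
from cdrflex.structure_io import Trajectory
from conftest import (
    backbone_structure,
    horn_min_rmsd,
    make_ca_structure,
    make_ca_trajectory,
)


class TestPairDistance:
    def test_three_four_five(self):
        traj = make_ca_trajectory([[[0, 0, 0], [3, 4, 0], [1, 1, 1]]])
        d = pair_distance_series(traj, ("A", 1), ("A", 2))
        np.testing.assert_allclose(d, [5.0])

    def test_coincident_atoms(self):
        traj = make_ca_trajectory([[[1, 2, 3], [1, 2, 3], [0, 0, 0]]])
        assert pair_distance_series(traj, ("A", 1), ("A", 2))[0] == 0.0

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(scale=8, size=(100, 5, 3))
        traj = make_ca_trajectory(frames)
        d = pair_distance_series(traj, ("A", 2), ("A", 5))
        expect = np.sqrt(((frames[:, 1] - frames[:, 4]) ** 2).sum(axis=1))
        np.testing.assert_allclose(d, expect, atol=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        frames = rng.normal(size=(10, 4, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
        moved = frames @ rot.T + np.array([5.0, -3.0, 1.0])
        d1 = pair_distance_series(make_ca_trajectory(frames), ("A", 1), ("A", 4))
        d2 = pair_distance_series(make_ca_trajectory(moved), ("A", 1), ("A", 4))
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestKabsch:
    def test_identity_on_self(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        rot, trans, fitted = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)
        np.testing.assert_allclose(fitted, pts, atol=1e-9)

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(8, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot90.T + np.array([1.0, -2.0, 3.0])
        _, _, fitted = kabsch_superpose(mobile, ref)
        assert rmsd(fitted, ref, superpose=False) < 1e-9

    def test_proper_rotation_under_reflection_pressure(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(6, 3))
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_instances(self):
        """SVD-Kabsch minimum equals Horn's quaternion closed form."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            mobile = rng.normal(size=(6, 3))
            ref = rng.normal(size=(6, 3))
            assert rmsd(mobile, ref) == pytest.approx(
                horn_min_rmsd(mobile, ref), abs=1e-6)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(6)
        mobile = rng.normal(size=(10, 3))
        ref = rng.normal(size=(10, 3))
        rot, _, _ = kabsch_superpose(mobile, ref)
        r_scipy, _ = Rotation.align_vectors(
            ref - ref.mean(axis=0), mobile - mobile.mean(axis=0))
        np.testing.assert_allclose(rot, r_scipy.as_matrix(), atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line[::-1])


class TestRMSD:
    def _reference_and_traj(self, n_frames=5, n_res=6, drift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ref = rng.normal(scale=4, size=(n_res, 3))
        frames = np.stack([
            ref + drift * t * rng.normal(size=(n_res, 3)) for t in range(n_frames)
        ])
        return make_ca_structure(ref), make_ca_trajectory(frames)

    def test_self_trajectory_is_zero(self):
        ref, traj = self._reference_and_traj(drift=0.0)
        sel = list(ref.residues)
        np.testing.assert_allclose(rmsd_series(traj, ref, sel), 0.0, atol=1e-9)

    def test_superposition_removes_rigid_motion(self):
        rng = np.random.default_rng(8)
        ref_coords = rng.normal(scale=4, size=(6, 3))
        ref = make_ca_structure(ref_coords)
        frames = np.stack([
            ref_coords @ Rotation.from_euler("x", 30 * t, degrees=True
                                             ).as_matrix().T + t
            for t in range(1, 5)
        ])
        traj = make_ca_trajectory(frames)
        sel = list(ref.residues)
        fitted = rmsd_series(traj, ref, sel, superpose=True)
        raw = rmsd_series(traj, ref, sel, superpose=False)
        np.testing.assert_allclose(fitted, 0.0, atol=1e-9)
        assert (raw > 0.1).all()

    def test_fit_never_increases_rmsd(self):
        ref, traj = self._reference_and_traj(drift=0.3, seed=9)
        sel = list(ref.residues)
        fitted = rmsd_series(traj, ref, sel, superpose=True)
        raw = rmsd_series(traj, ref, sel, superpose=False)
        assert (fitted <= raw + 1e-12).all()

    def test_symmetry_after_fitting(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-9)

    def test_matches_brute_force_per_frame(self):
        ref, traj = self._reference_and_traj(drift=0.5, seed=11)
        sel = list(ref.residues)
        got = rmsd_series(traj, ref, sel, superpose=True)
        ref_coords = np.asarray([r.atom("CA").xyz for r in sel])
        expect = [horn_min_rmsd(traj.frames[t], ref_coords)
                  for t in range(traj.n_frames)]
        np.testing.assert_allclose(got, expect, atol=1e-9)


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(scale=4, size=(6, 3))
        ref = make_ca_structure(coords)
        traj = make_ca_trajectory(np.stack([coords] * 8))
        out = rmsf_profile(traj, ref, list(ref.residues))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_alternating_atom_has_unit_rmsf(self):
        # a large cloud of fixed anchor atoms pins the fit (the moving
        # atom contributes ~1/n to the centroid); one atom toggles ref±1
        rng = np.random.default_rng(13)
        coords = rng.normal(scale=20, size=(200, 3))
        frames = []
        for t in range(40):
            f = coords.copy()
            f[0, 0] += 1.0 if t % 2 == 0 else -1.0
            frames.append(f)
        ref = make_ca_structure(coords)
        traj = make_ca_trajectory(np.stack(frames))
        out = rmsf_profile(traj, ref, list(ref.residues))
        assert out[0] == pytest.approx(1.0, abs=0.05)
        assert (out[1:] < 0.05).all()

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(14)
        base = rng.normal(scale=5, size=(6, 3))
        frames = base + 0.3 * rng.normal(size=(50, 6, 3))
        ref = make_ca_structure(base)
        traj = make_ca_trajectory(frames)
        got = rmsf_profile(traj, ref, list(ref.residues))
        sq = np.zeros(6)
        for t in range(50):
            _, _, fitted = kabsch_superpose(frames[t], base)
            for i in range(6):
                sq[i] += np.sum((fitted[i] - base[i]) ** 2)
        np.testing.assert_allclose(got, np.sqrt(sq / 50), atol=1e-9)

    def test_single_frame_allowed(self):
        rng = np.random.default_rng(15)
        base = rng.normal(size=(5, 3))
        ref = make_ca_structure(base)
        traj = make_ca_trajectory(base[None] + 0.1)
        out = rmsf_profile(traj, ref, list(ref.residues))
        assert out.shape == (5,)


def _projection_dihedral(p1, p2, p3, p4):
    """Independent torsion formula: project the outer bonds onto the
    plane normal to the central bond (praxeolitic construction)."""
    b0, b1, b2 = p1 - p2, p3 - p2, p4 - p3
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return np.degrees(np.arctan2(y, x))


class TestDihedral:
    def test_planar_trans_is_180(self):
        pts = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], float)
        assert dihedral(*pts) == pytest.approx(180.0, abs=1e-9)

    def test_planar_cis_is_zero(self):
        pts = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        assert dihedral(*pts) == pytest.approx(0.0, abs=1e-9)

    def test_out_of_plane_quarter_turn(self):
        p1 = np.array([0.0, 1.0, 0.0])
        p2 = np.array([0.0, 0.0, 0.0])
        p3 = np.array([1.0, 0.0, 0.0])
        p4 = np.array([1.0, 0.0, 1.0])
        got = dihedral(p1, p2, p3, p4)
        assert abs(got) == pytest.approx(90.0, abs=1e-9)
        assert got == pytest.approx(_projection_dihedral(p1, p2, p3, p4), abs=1e-9)

    def test_matches_projection_formula_on_random_points(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            pts = rng.normal(size=(4, 3))
            assert dihedral(*pts) == pytest.approx(
                _projection_dihedral(*pts), abs=1e-9)

    def test_degenerate_raises(self):
        p = np.zeros(3)
        with pytest.raises(DegenerateGeometryError):
            dihedral(p, p, np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))
        line = [np.array([float(i), 0, 0]) for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            dihedral(*line)


class TestPhiPsiSeries:
    def _as_traj(self, struct):
        return Trajectory(struct, struct.coordinates()[None], [0.0])

    def test_ideal_helix_recovered(self):
        struct = backbone_structure([(-57.0, -47.0)] * 6)
        table, _ = phi_psi_series(self._as_traj(struct), "A")
        inner = table[(table["residue_number"] > 1)
                      & (table["residue_number"] < 6)]
        np.testing.assert_allclose(inner["phi"], -57.0, atol=1e-3)
        np.testing.assert_allclose(inner["psi"], -47.0, atol=1e-3)

    def test_termini_yield_nan(self):
        struct = backbone_structure([(-57.0, -47.0)] * 2)
        table, report = phi_psi_series(self._as_traj(struct), "A")
        r1 = table[table["residue_number"] == 1].iloc[0]
        r2 = table[table["residue_number"] == 2].iloc[0]
        assert np.isnan(r1["phi"]) and not np.isnan(r1["psi"])
        assert not np.isnan(r2["phi"]) and np.isnan(r2["psi"])
        reasons = {r for _, r in report}
        assert any("N-terminal" in r for r in reasons)

    def test_ca_only_chain_all_absent_with_report(self):
        traj = make_ca_trajectory(np.random.default_rng(17).normal(size=(1, 4, 3)))
        table, report = phi_psi_series(traj, "A")
        assert table["phi"].isna().all() and table["psi"].isna().all()
        assert len(report) == 4
        assert all("missing backbone" in reason for _, reason in report)


class TestClassifySS:
    @pytest.mark.parametrize("phi,psi,expect", [
        (-57.0, -47.0, "rh_helix"),
        (57.0, 47.0, "lh_helix"),
        (-120.0, 135.0, "beta"),
        (-120.0, -170.0, "beta"),
        (0.0, 0.0, "other"),
        (180.0, 180.0, "other"),
    ])
    def test_canonical_angles(self, phi, psi, expect):
        assert classify_ss(phi, psi) == expect

    @settings(max_examples=300, derandomize=True)
    @given(
        phi=st.floats(min_value=-179.999, max_value=180.0),
        psi=st.floats(min_value=-179.999, max_value=180.0),
    )
    def test_total_function_with_disjoint_regions(self, phi, psi):
        """Each angle pair lands in exactly one region (independently
        re-derived rectangle membership)."""
        motif = classify_ss(phi, psi)
        in_rh = -100 <= phi < -30 and -80 <= psi < -5
        in_lh = 30 < phi <= 100 and 5 < psi <= 80
        in_beta = -180 <= phi < -45 and (90 <= psi <= 180 or psi < -150)
        memberships = [in_rh, in_lh, in_beta]
        assert sum(memberships) <= 1
        expected = (
            "rh_helix" if in_rh else "lh_helix" if in_lh
            else "beta" if in_beta else "other"
        )
        assert motif == expected


class TestCountSS:
    def _angle_table(self, per_frame_angles):
        import pandas as pd

        rows = []
        for f, angles in enumerate(per_frame_angles):
            for i, (phi, psi) in enumerate(angles):
                rows.append((f, 0.5 * f, i + 1, phi, psi))
        return pd.DataFrame(
            rows, columns=["frame", "time_ns", "residue_number", "phi", "psi"])

    def test_pure_composition_counted(self):
        angles = [(-120, 135)] * 7 + [(-57, -47)] * 3
        table = self._angle_table([angles, angles])
        counts = count_ss_residues(table)
        assert (counts.counts["beta"] == 7).all()
        assert (counts.counts["rh_helix"] == 3).all()
        assert (counts.counts["lh_helix"] == 0).all()

    def test_all_other_angles(self):
        table = self._angle_table([[(0, 0)] * 5])
        counts = count_ss_residues(table)
        assert counts.counts.to_numpy().sum() == 0

    def test_window_means_hand_computed(self):
        frame0 = [(-120, 135), (-120, 135), (-57, -47)]
        frame1 = [(-120, 135), (0, 0), (57, 47)]
        counts = count_ss_residues(self._angle_table([frame0, frame1]))
        means = counts.window_means
        assert means["beta"] == pytest.approx((2 + 1) / 2)
        assert means["rh_helix"] == pytest.approx(0.5)
        assert means["lh_helix"] == pytest.approx(0.5)

    def test_region_restriction(self):
        angles = [(-57, -47)] * 6
        table = self._angle_table([angles])
        counts = count_ss_residues(table, region_residue_numbers={1, 2},
                                   region_name="sub")
        assert counts.counts["rh_helix"].iloc[0] == 2


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = fit_linear(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_y_convention(self):
        slope, intercept, r2 = fit_linear(np.arange(5.0), np.full(5, 3.0))
        assert (slope, intercept, r2) == (0.0, 3.0, 0.0)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_linear(np.full(5, 2.0), np.arange(5.0))

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=200)
        y = 1.7 * x - 0.4 + rng.normal(scale=0.5, size=200)
        slope, intercept, r2 = fit_linear(x, y)
        a = np.vstack([x, np.ones_like(x)]).T
        beta, res, *_ = np.linalg.lstsq(a, y, rcond=None)
        assert slope == pytest.approx(beta[0], abs=1e-9)
        assert intercept == pytest.approx(beta[1], abs=1e-9)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(1 - res[0] / ss_tot, abs=1e-9)
        assert 0.0 <= r2 <= 1.0
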