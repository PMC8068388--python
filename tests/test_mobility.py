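"""Trajectory analytics: I/O, Kabsch, RMSD/RMSF, PCA, ΔRMSF, salt bridges."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from biphasekit import (
    Trajectory,
    classify_mobility,
    delta_rmsf,
    kabsch_superpose,
    pca_modes,
    read_trajectory,
    rmsd_series,
    rmsf_profile,
    salt_bridge_occupancy,
    simulate_trajectory,
    write_trajectory,
)
from biphasekit.mobility import MobilityProfile

# a hand-typed 2-frame, 3-atom multi-model PDB (coordinates chosen by hand)
HAND_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.000   8.000   9.500  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       1.100   2.000   3.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.000   5.250   6.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.000   8.000   9.000  1.00  0.00           C
ENDMDL
END
"""


def rigid_copy(traj: Trajectory, seed=0) -> Trajectory:
    rng = np.random.default_rng(seed)
    coords = traj.coords.copy()
    for f in range(traj.n_frames):
        R = Rotation.random(rng=rng).as_matrix()
        coords[f] = coords[f] @ R.T + rng.uniform(-30, 30, 3)
    return Trajectory(coords, traj.res_ids, traj.res_names, traj.atom_names, traj.chain_ids)


class TestIO:
    def test_hand_written_pdb_parses_to_typed_values(self, tmp_path):
        p = tmp_path / "hand.pdb"
        p.write_text(HAND_PDB)
        traj = read_trajectory(p)
        assert traj.n_frames == 2 and traj.n_atoms == 3
        np.testing.assert_allclose(traj.coords[0, 0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(traj.coords[1, 1], [4.0, 5.25, 6.0])
        assert list(traj.res_ids) == [1, 2, 3]
        assert set(traj.atom_names) == {"CA"}

    def test_write_read_write_is_byte_stable(self, tmp_path):
        traj = simulate_trajectory(6, 4, 0.4, seed=2)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_trajectory(traj, p1)
        write_trajectory(read_trajectory(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_metadata(self, tmp_path):
        traj = simulate_trajectory(5, 3, 0.2, seed=0)
        p = tmp_path / "t.pdb"
        write_trajectory(traj, p)
        back = read_trajectory(p)
        np.testing.assert_array_equal(back.res_ids, traj.res_ids)
        np.testing.assert_array_equal(back.atom_names, traj.atom_names)
        np.testing.assert_allclose(back.coords, traj.coords, atol=5e-3)

    def test_single_model_rejected(self, tmp_path):
        single = HAND_PDB.split("MODEL        2")[0] + "END\n"
        p = tmp_path / "one.pdb"
        p.write_text(single)
        with pytest.raises(ValueError, match="2 MODEL"):
            read_trajectory(p)

    def test_xyz_round_trip(self, tmp_path):
        p = tmp_path / "t.xyz"
        p.write_text(
            "3\nframe 0\nC 0.0 0.0 0.0\nC 1.5 0.0 0.0\nC 0.0 2.0 0.0\n"
            "3\nframe 1\nC 0.1 0.0 0.0\nC 1.5 0.1 0.0\nC 0.0 2.0 0.1\n"
        )
        traj = read_trajectory(p)
        assert traj.n_frames == 2 and traj.n_atoms == 3
        np.testing.assert_allclose(traj.coords[1, 0], [0.1, 0.0, 0.0])

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_trajectory("/nonexistent/file.pdb")

    def test_trajectory_validation(self):
        with pytest.raises(ValueError, match="2 frames"):
            Trajectory(
                np.zeros((1, 3, 3)), np.arange(3), np.full(3, "ALA"),
                np.full(3, "CA"), np.full(3, "A"),
            )


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3)) * 5
        R_true = Rotation.random(rng=rng).as_matrix()
        t_true = np.array([3.0, -7.0, 11.0])
        moved = pts @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, R_true, atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_beats_random_rotation_search(self):
        # stochastic oracle: no sampled rotation does better
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3)) * 3
        b = rng.normal(size=(10, 3)) * 3
        _, _, rmsd = kabsch_superpose(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        rots = Rotation.random(20_000, random_state=3)
        best = min(
            np.sqrt(((ac @ R.T - bc) ** 2).sum(axis=1).mean())
            for R in rots.as_matrix()
        )
        assert rmsd <= best + 1e-12

    def test_symmetry_and_prerotation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        _, _, r_ab = kabsch_superpose(a, b)
        _, _, r_ba = kabsch_superpose(b, a)
        assert r_ab == pytest.approx(r_ba, rel=1e-10)
        Rpre = Rotation.random(1, random_state=5).as_matrix()[0]
        _, _, r_rot = kabsch_superpose(a @ Rpre.T, b)
        assert r_rot == pytest.approx(r_ab, rel=1e-10)

    def test_degenerate_sets_flagged(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSD:
    def test_static_trajectory_all_zero(self):
        traj = simulate_trajectory(10, 6, 0.0, seed=0)
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_reference_frame_entry_is_zero(self):
        traj = simulate_trajectory(10, 6, 0.5, seed=1)
        assert rmsd_series(traj, reference_frame=0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_step_displacement_closed_form(self):
        # one atom moved by d at frame k: RMSD jumps by ~d/sqrt(n)
        n, d, k = 100, 5.0, 3
        traj = simulate_trajectory(n, 6, 0.0, seed=0)
        coords = traj.coords.copy()
        coords[k:, 0, 2] += d
        moved = Trajectory(coords, traj.res_ids, traj.res_names,
                           traj.atom_names, traj.chain_ids)
        series = rmsd_series(moved)
        assert series[k - 1] == pytest.approx(0.0, abs=1e-12)
        assert series[k] == pytest.approx(d / np.sqrt(n), rel=0.03)

    def test_empty_selection_rejected(self):
        traj = simulate_trajectory(5, 4, 0.1, seed=0)
        with pytest.raises(ValueError, match="selection"):
            rmsd_series(traj, selection="CB")


class TestRMSF:
    def test_static_trajectory_zero_profile(self):
        traj = simulate_trajectory(12, 5, 0.0, seed=0)
        assert np.allclose(rmsf_profile(traj).rmsf, 0.0)

    def test_pure_rigid_motion_removed_by_superposition(self):
        base = simulate_trajectory(12, 40, 0.0, seed=0)
        moved = rigid_copy(base, seed=1)
        assert np.all(rmsf_profile(moved).rmsf < 1e-8)

    def test_rigid_transform_invariance(self):
        traj = simulate_trajectory(15, 200, np.linspace(0.2, 1.0, 15), seed=2)
        moved = rigid_copy(traj, seed=3)
        np.testing.assert_allclose(
            rmsf_profile(moved).rmsf, rmsf_profile(traj).rmsf, atol=1e-8
        )


class TestPCA:
    def test_single_coordinate_motion_single_mode(self):
        # 200 static anchor atoms keep superposition leakage of the single
        # moving coordinate negligible: one dominant eigenvalue remains
        traj = simulate_trajectory(200, 50, 0.0, seed=0)
        coords = traj.coords.copy()
        coords[:, 2, 0] += np.sin(np.linspace(0, 4 * np.pi, 50))
        t = Trajectory(coords, traj.res_ids, traj.res_names,
                       traj.atom_names, traj.chain_ids)
        res = pca_modes(t, selection=None, k=5)
        assert res.eigenvalues[0] > 1e-4
        assert np.all(res.eigenvalues[1:] < res.eigenvalues[0] * 1e-6)

    def test_eigenvalue_sum_equals_total_variance(self):
        traj = simulate_trajectory(8, 300, np.linspace(0.1, 0.9, 8), seed=4)
        res = pca_modes(traj, k=3)
        from biphasekit.mobility import _superpose_frames

        sel = traj.select("CA")
        aligned = _superpose_frames(traj, sel)[:, sel]
        dev = aligned - aligned.mean(axis=0)
        total_var = (dev**2).sum(axis=(1, 2)).mean()
        assert res.eigenvalues.sum() == pytest.approx(total_var, rel=1e-10)

    def test_matches_dense_covariance_eigensolve(self):
        traj = simulate_trajectory(5, 100, 0.5, seed=5)
        res = pca_modes(traj, selection=None, k=15)
        from biphasekit.mobility import _superpose_frames

        aligned = _superpose_frames(traj, np.arange(5))
        X = aligned.reshape(100, 15)
        X = X - X.mean(axis=0)
        cov = X.T @ X / 100
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(res.eigenvalues, eig, atol=1e-10)

    def test_k_exceeding_dimensions_rejected(self):
        traj = simulate_trajectory(4, 10, 0.2, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            pca_modes(traj, k=13)

    def test_rigid_transform_invariance_of_eigenvalues(self):
        traj = simulate_trajectory(10, 150, 0.6, seed=6)
        moved = rigid_copy(traj, seed=7)
        a = pca_modes(traj, k=3).eigenvalues
        b = pca_modes(moved, k=3).eigenvalues
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestClassifyMobility:
    def test_uniform_profile_single_class(self):
        assert set(classify_mobility(np.full(10, 0.7))) == {"low"}

    def test_strictly_increasing_two_per_class(self):
        labels = classify_mobility(np.arange(1.0, 9.0))
        assert list(labels) == ["low"] * 2 + ["intermediate"] * 2 + ["high"] * 2 + ["highest"] * 2

    def test_matches_brute_force_quartiles(self):
        rng = np.random.default_rng(8)
        r = rng.uniform(0.1, 3.0, 40)
        labels = classify_mobility(r)
        q1, q2, q3 = np.quantile(r, [0.25, 0.5, 0.75])
        for val, lab in zip(r, labels):
            if val <= q1:
                assert lab == "low"
            elif val <= q2:
                assert lab == "intermediate"
            elif val <= q3:
                assert lab == "high"
            else:
                assert lab == "highest"


class TestDeltaRMSF:
    def test_identical_profiles_zero(self):
        traj = simulate_trajectory(10, 100, 0.5, seed=9)
        prof = rmsf_profile(traj)
        d = delta_rmsf(prof, prof)
        assert np.allclose(d.delta, 0.0)
        assert d.decrease_runs == []

    def test_damped_region_reported(self):
        # residues 10-20 damped by 50 % in the generator (drug-bound analog)
        sigma = np.full(30, 1.0)
        damped = sigma.copy()
        damped[9:20] *= 0.5
        a = rmsf_profile(simulate_trajectory(30, 3000, sigma, seed=10))
        b = rmsf_profile(simulate_trajectory(30, 3000, damped, seed=11))
        d = delta_rmsf(a, b, threshold=0.2)
        assert len(d.decrease_runs) == 1
        start, end, total = d.decrease_runs[0]
        assert (start, end) == (10, 20)
        assert total < 0

    def test_mismatched_residues_rejected(self):
        a = MobilityProfile(np.arange(1, 6), np.ones(5), np.full(5, "low"))
        b = MobilityProfile(np.arange(2, 7), np.ones(5), np.full(5, "low"))
        with pytest.raises(ValueError, match="residue"):
            delta_rmsf(a, b)


def make_bridge_traj(distances: list[float]) -> Trajectory:
    """One ASP OD1 / LYS NZ pair, NZ at the given distance per frame."""
    n_frames = len(distances)
    coords = np.zeros((n_frames, 4, 3))
    coords[:, 0] = [0.0, 0.0, 0.0]          # ASP CA
    coords[:, 1] = [1.0, 0.0, 0.0]          # ASP OD1
    coords[:, 2] = [10.0, 10.0, 0.0]        # LYS CA
    for f, d in enumerate(distances):
        coords[f, 3] = [1.0 + d, 0.0, 0.0]  # LYS NZ
    return Trajectory(
        coords,
        res_ids=np.array([1, 1, 2, 2]),
        res_names=np.array(["ASP", "ASP", "LYS", "LYS"]),
        atom_names=np.array(["CA", "OD1", "CA", "NZ"]),
        chain_ids=np.full(4, "A"),
    )


class TestSaltBridges:
    def test_contact_within_cutoff_full_occupancy(self):
        traj = make_bridge_traj([3.5, 3.5])
        df = salt_bridge_occupancy(traj, cutoff=4.0)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row["acid_res_name"], row["base_res_name"]) == ("ASP", "LYS")
        assert row["occupancy"] == 1.0

    def test_contact_beyond_cutoff_not_reported(self):
        traj = make_bridge_traj([6.0, 6.0])
        assert salt_bridge_occupancy(traj, cutoff=4.0).empty

    def test_partial_occupancy_fraction(self):
        traj = make_bridge_traj([3.0] * 5 + [8.0] * 5)
        df = salt_bridge_occupancy(traj, cutoff=4.0)
        assert df.iloc[0]["occupancy"] == pytest.approx(0.5)

    def test_calpha_only_warns_and_returns_empty(self):
        traj = simulate_trajectory(5, 3, 0.1, seed=0)
        with pytest.warns(UserWarning, match="salt-bridge"):
            df = salt_bridge_occupancy(traj)
        assert df.empty
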