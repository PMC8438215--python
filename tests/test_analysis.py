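"""Pose clustering, noise filtering, metastable events, landscapes, energies."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.pairwise import cosine_similarity

import sumdkit as sk
from sumdkit.analysis import PoseMatrix, events_to_frame


def make_pose_matrix(rows: np.ndarray, stride: int = 1) -> PoseMatrix:
    n = rows.shape[0]
    prov = pd.DataFrame({"tag": ["t"] * n, "frame_index": np.arange(n),
                         "time_ps": np.arange(1.0, n + 1)})
    return PoseMatrix(rows=rows, provenance=prov, stride=stride,
                      n_ligand_atoms=rows.shape[1] // 3)


class TestBuildPoseMatrix:
    def test_stride_and_row_count(self, funnel_spec, funnel_structure):
        base = funnel_spec.bound_pose_frame()
        rg = np.random.default_rng(1)
        mk = lambda: sk.Trajectory(
            coords=base[None] + rg.normal(0, 0.1, (100, funnel_spec.n_atoms, 3)),
            times_ps=np.arange(1.0, 101))
        fit = sk.AtomSelection.from_indices(np.arange(funnel_spec.n_receptor))
        pm = sk.build_pose_matrix([mk(), mk()], funnel_structure, base,
                                  funnel_spec.ligand_selection(), fit, stride=10)
        assert pm.n_rows == 20
        assert pm.rows.shape[1] == 3 * funnel_spec.n_ligand

    def test_identical_frames_give_identical_rows(self, funnel_spec, funnel_structure):
        base = funnel_spec.bound_pose_frame()
        traj = sk.Trajectory(coords=np.repeat(base[None], 5, axis=0),
                             times_ps=np.arange(1.0, 6))
        fit = sk.AtomSelection.from_indices(np.arange(funnel_spec.n_receptor))
        pm = sk.build_pose_matrix([traj], funnel_structure, base,
                                  funnel_spec.ligand_selection(), fit, stride=1)
        assert pm.n_rows == 5
        assert np.allclose(pm.rows, pm.rows[0])

    def test_alignment_removes_rigid_motion(self, funnel_spec, funnel_structure):
        from sumdkit.toysim import _random_rotation

        base = funnel_spec.bound_pose_frame()
        frames = [base]
        for k in range(3):
            rg = np.random.default_rng(k)
            rot = _random_rotation(rg)
            frames.append(base @ rot.T + rg.normal(0, 5, 3))
        traj = sk.Trajectory(coords=np.array(frames), times_ps=np.arange(1.0, 5))
        fit = sk.AtomSelection.from_indices(np.arange(funnel_spec.n_receptor))
        pm = sk.build_pose_matrix([traj], funnel_structure, base,
                                  funnel_spec.ligand_selection(), fit, stride=1)
        assert np.allclose(pm.rows, pm.rows[0], atol=1e-9)


class TestNoiseFilter:
    def test_identical_rows_never_noise(self):
        rows = np.tile(np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]), (6, 1))
        pm = make_pose_matrix(rows)
        kept, noise = sk.filter_noise_cosine(pm, similarity_threshold=1.0,
                                             neighbor_count=3)
        assert noise.size == 0
        assert kept.n_rows == 6

    def test_orthogonal_outlier_flagged(self):
        # a tight bundle plus one row orthogonal (after row-centering) to it;
        # verified against brute-force pairwise cosines
        rg = np.random.default_rng(4)
        base = np.array([1.0, -1.0, 0.0, 0.0, 0.0, 0.0])
        bundle = base + rg.normal(0, 0.01, (10, 6))
        outlier = np.array([0.0, 0.0, 1.0, -1.0, 0.0, 0.0])
        rows = np.vstack([bundle, outlier])
        pm = make_pose_matrix(rows)
        kept, noise = sk.filter_noise_cosine(pm, similarity_threshold=0.01,
                                             neighbor_count=5)
        centered = rows - rows.mean(axis=1, keepdims=True)
        sims = cosine_similarity(centered)
        np.fill_diagonal(sims, -np.inf)
        expected_noise = np.flatnonzero(sims.max(axis=1) < 0.01)
        assert noise.tolist() == expected_noise.tolist() == [10]
        assert kept.n_rows == 10

    def test_threshold_zero_keeps_positively_similar_rows(self):
        rg = np.random.default_rng(7)
        rows = np.abs(rg.normal(1, 0.3, (12, 9)))  # nonnegative construction
        rows = np.sort(rows, axis=1)               # mutually positively correlated
        pm = make_pose_matrix(rows)
        _, noise = sk.filter_noise_cosine(pm, similarity_threshold=0.0,
                                          neighbor_count=4)
        assert noise.size == 0

    def test_k_too_large_rejected(self):
        pm = make_pose_matrix(np.random.default_rng(0).normal(0, 1, (4, 6)))
        with pytest.raises(ValueError):
            sk.filter_noise_cosine(pm, neighbor_count=4)


class TestClustering:
    def planted(self, seed=2, n_per=50, sigma=0.3, sep=5.0):
        rg = np.random.default_rng(seed)
        centers = np.array([[0.0, 0, 0, 0, 0, 0],
                            [sep, 0, 0, sep, 0, 0],
                            [0, sep, 0, 0, sep, 0]])
        rows, labels = [], []
        for c, center in enumerate(centers):
            rows.append(center + rg.normal(0, sigma, (n_per, 6)))
            labels += [c] * n_per
        return np.vstack(rows), np.array(labels)

    def test_recovers_planted_clusters(self):
        rows, truth = self.planted()
        cl = sk.cluster_poses(make_pose_matrix(rows), min_samples=10)
        assert adjusted_rand_score(truth, cl.labels) >= 0.9

    def test_all_identical_single_cluster(self):
        rows = np.tile(np.arange(6.0), (20, 1))
        cl = sk.cluster_poses(make_pose_matrix(rows), min_samples=5)
        assert np.all(cl.labels == 0)

    def test_uniform_random_is_all_noise(self):
        # no dense region: nearest-neighbour spacing is comparable to the
        # domain scale, so a strict min_samples marks everything noise
        rg = np.random.default_rng(9)
        rows = rg.uniform(0, 100, (30, 6))
        cl = sk.cluster_poses(make_pose_matrix(rows), min_samples=15, max_eps=5.0)
        assert np.all(cl.labels == -1)

    def test_permutation_invariance(self):
        rows, _ = self.planted(seed=12)
        pm = make_pose_matrix(rows)
        cl = sk.cluster_poses(pm, min_samples=10)
        rg = np.random.default_rng(3)
        perm = rg.permutation(rows.shape[0])
        cl_p = sk.cluster_poses(make_pose_matrix(rows[perm]), min_samples=10)
        assert adjusted_rand_score(cl.labels[perm], cl_p.labels) == pytest.approx(1.0)


class TestRepresentatives:
    def test_argmin_rule(self):
        rows = np.vstack([np.zeros((3, 6)), np.ones((2, 6))])
        cl = sk.cluster_poses(make_pose_matrix(rows), min_samples=2)
        energies = np.array([-5.0, -10.0, -7.0, -1.0, -2.0])
        done = sk.rank_cluster_representatives(cl, energies)
        t = done.table.set_index("cluster_id")
        first = t.loc[done.labels[0]]
        assert first["representative_row"] == 1
        assert first["min_energy"] == -10.0
        assert first["mean_energy"] == pytest.approx(np.mean([-5, -10, -7]))

    def test_no_member_beats_representative(self, campaign20, funnel_spec,
                                            funnel_structure):
        table, results = campaign20
        trajs = [r.trajectory for r in results if r is not None and r.trajectory is not None]
        fit = sk.AtomSelection.from_indices(np.arange(funnel_spec.n_receptor))
        pm = sk.build_pose_matrix(trajs, funnel_structure,
                                  funnel_spec.bound_pose_frame(),
                                  funnel_spec.ligand_selection(), fit, stride=10)
        kept, noise = sk.filter_noise_cosine(pm)
        cl = sk.cluster_poses(kept, min_samples=10)
        scorer = sk.NonbondedScorer(funnel_spec)
        energies = np.concatenate([scorer.score_trajectory(t)[::10] for t in trajs])
        keep_idx = np.setdiff1d(np.arange(pm.n_rows), noise)
        done = sk.rank_cluster_representatives(cl, energies[keep_idx])
        kept_e = energies[keep_idx]
        for _, row in done.table.iterrows():
            members = np.flatnonzero(done.labels == row["cluster_id"])
            assert kept_e[int(row["representative_row"])] == pytest.approx(
                kept_e[members].min())

    def test_missing_energies_listed(self):
        rows = np.vstack([np.zeros((3, 6)), np.ones((3, 6))])
        cl = sk.cluster_poses(make_pose_matrix(rows), min_samples=2)
        energies = np.array([0.0, np.nan, 1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="1"):
            sk.rank_cluster_representatives(cl, energies)

    def test_table_report_rounds_to_integer(self):
        rows = np.vstack([np.zeros((3, 6)), np.ones((3, 6))])
        cl = sk.cluster_poses(make_pose_matrix(rows), min_samples=2)
        done = sk.rank_cluster_representatives(
            cl, np.array([-27.2, -27.4, -27.3, -32.1, -32.3, -32.2]))
        rep = done.table_report()
        assert set(rep.columns) == {"cluster", "n_frames", "mean_dG_kcal_mol_rounded"}
        assert sorted(rep["mean_dG_kcal_mol_rounded"]) == [-32, -27]
        assert rep["cluster"].min() == 1


class TestMetastableEvents:
    def synthetic_profile(self):
        # 40 Å -> plateau at 15 Å (10 ns) -> descent -> plateau at 3 Å
        t, d = [], []
        tt = 0.0
        for v in np.linspace(40, 15.5, 20):
            t.append(tt); d.append(v); tt += 100.0
        for _ in range(100):          # 10 ns plateau at ~15
            t.append(tt); d.append(15.0 + 0.3 * np.sin(tt)); tt += 100.0
        for v in np.linspace(14.5, 3.5, 20):
            t.append(tt); d.append(v); tt += 100.0
        for _ in range(60):           # bound plateau at 3
            t.append(tt); d.append(3.0 + 0.2 * np.sin(tt)); tt += 100.0
        return np.array(t), np.array(d)

    def test_single_planted_plateau(self):
        t, d = self.synthetic_profile()
        evs = sk.detect_metastable_events(t, d, min_residence_ps=5000.0,
                                          dcm_band=2.0, exclude_below=5.0)
        assert len(evs) == 1
        assert evs[0].median_dcm == pytest.approx(15.0, abs=1.0)
        assert evs[0].residence_ps >= 5000.0

    def test_monotone_descent_no_events(self):
        t = np.arange(0.0, 100.0)
        d = np.linspace(40, 5, 100)
        assert sk.detect_metastable_events(t, d, min_residence_ps=10.0,
                                           dcm_band=0.5, exclude_below=5.0) == []

    def test_two_plateaus_in_time_order(self):
        t, d = [], []
        tt = 0.0
        for v in np.linspace(40, 12.5, 10):
            t.append(tt); d.append(v); tt += 100.0
        for _ in range(80):   # 8 ns at 12
            t.append(tt); d.append(12.0); tt += 100.0
        for v in np.linspace(11.5, 7.5, 10):
            t.append(tt); d.append(v); tt += 100.0
        for _ in range(60):   # 6 ns at 7
            t.append(tt); d.append(7.0); tt += 100.0
        evs = sk.detect_metastable_events(np.array(t), np.array(d),
                                          min_residence_ps=5000.0,
                                          dcm_band=1.0, exclude_below=5.0)
        assert len(evs) == 2
        assert evs[0].median_dcm == pytest.approx(12.0, abs=0.6)
        assert evs[1].median_dcm == pytest.approx(7.0, abs=0.6)
        assert evs[0].end_ps <= evs[1].start_ps

    def test_invariants_on_random_series(self):
        rg = np.random.default_rng(17)
        for _ in range(10):
            t = np.arange(0.0, 200.0)
            d = np.abs(rg.normal(12, 4, 200)).cumsum() / np.arange(1, 201) + 2
            evs = sk.detect_metastable_events(t, d, min_residence_ps=20.0,
                                              dcm_band=1.5, exclude_below=5.0)
            for a, b in zip(evs, evs[1:]):
                assert a.end_ps <= b.start_ps
            for ev in evs:
                assert ev.median_dcm > 5.0
                assert ev.residence_ps >= 20.0
        frame = events_to_frame(evs)
        assert list(frame.columns)[:2] == ["start_ns", "end_ns"]


class TestLandscape:
    def test_single_frame_single_cell(self, funnel_spec, funnel_structure):
        frame = funnel_spec.bound_pose_frame()
        traj = sk.Trajectory(coords=frame[None], times_ps=[1.0])
        grid = sk.energy_landscape(traj, funnel_structure,
                                   funnel_spec.ligand_selection(),
                                   funnel_spec.site_selection(),
                                   sk.NonbondedScorer(funnel_spec),
                                   dcm_bins=10, energy_bins=10)
        assert grid.counts.sum() == 1
        assert np.count_nonzero(grid.counts) == 1

    def test_counts_conserve_frames(self, campaign20, funnel_spec, funnel_structure):
        _, results = campaign20
        traj = next(r.trajectory for r in results if r is not None)
        grid = sk.energy_landscape(traj, funnel_structure,
                                   funnel_spec.ligand_selection(),
                                   funnel_spec.site_selection(),
                                   sk.NonbondedScorer(funnel_spec))
        assert grid.n_frames == traj.n_frames

    def test_planted_wells_show_as_minima(self, funnel_spec, funnel_structure):
        # double-well run: dynamics started in the bound pose and in the
        # decoy pose; the per-dcm-bin minimum-energy profile must show a
        # well in each planted basin (± one bin)
        parts = []
        for pose in (funnel_spec.bound_pose, funnel_spec.decoy_poses[0]):
            coords = funnel_spec.initial_frame(pose)
            vel = np.zeros_like(coords)
            rg = np.random.default_rng(5)
            vel[funnel_spec.ligand_indices] = sk.maxwell_boltzmann_velocities(
                funnel_spec.ligand_mass, funnel_spec.temperature, rg)
            _, traj = sk.propagate_langevin(sk.SimState(coords, vel), funnel_spec,
                                            20_000, 50, seed=5)
            parts.append(traj.coords)
        merged = np.concatenate(parts)
        traj = sk.Trajectory(coords=merged, times_ps=np.arange(1.0, len(merged) + 1))
        grid = sk.energy_landscape(traj, funnel_structure,
                                   funnel_spec.ligand_selection(),
                                   funnel_spec.site_selection(),
                                   sk.NonbondedScorer(funnel_spec),
                                   dcm_bins=np.arange(2.0, 30.0, 2.0))
        centers = 0.5 * (grid.dcm_edges[:-1] + grid.dcm_edges[1:])
        prof = grid.min_energy_profile
        decoy_dcm = np.linalg.norm(funnel_spec.decoy_centers[0] - funnel_spec.site_center)
        bound_bin = int(np.nanargmin(np.abs(centers - 3.5)))
        decoy_bin = int(np.nanargmin(np.abs(centers - decoy_dcm)))
        assert np.nanargmin(prof) in (bound_bin - 1, bound_bin, bound_bin + 1)
        decoy_well = np.nanmin(prof[decoy_bin - 1:decoy_bin + 2])
        assert decoy_well < -2.5  # strongly favourable frames at the decoy distance


class TestEnergySummaries:
    def test_constant_scorer(self, funnel_spec, funnel_structure):
        frame = funnel_spec.bound_pose_frame()
        traj = sk.Trajectory(coords=np.repeat(frame[None], 5, 0),
                             times_ps=np.arange(1.0, 6))
        s = sk.binding_energy_summary(traj, (0.0, 1.0), np.full(5, -10.0))
        assert s.mean_kcal_mol == -10.0
        assert s.sd_kcal_mol == 0.0
        assert s.n_frames == 5

    def test_imported_csv_matches_hand_sum(self, funnel_spec, tmp_path):
        vals = [-20.0, -25.0, -30.0, -27.0]
        df = pd.DataFrame({"frame_index": range(4), "time_ns": np.arange(4) * 0.1,
                           "dG_kcal_mol": vals})
        p = tmp_path / "e.csv"
        df.to_csv(p, index=False)
        scorer = sk.TableScorer.from_csv(p)
        frame = funnel_spec.bound_pose_frame()
        traj = sk.Trajectory(coords=np.repeat(frame[None], 4, 0),
                             times_ps=np.arange(1.0, 5))
        s = sk.binding_energy_summary(traj, (0.0, 1.0), scorer)
        assert s.mean_kcal_mol == pytest.approx(sum(vals) / 4)
        assert s.scorer == "imported-table"

    def test_ddg_five_kcal_rule(self):
        ddg, meaningful = sk.ddg_comparison(-27.3, -32.2)
        assert abs(ddg) == pytest.approx(4.9)
        assert not meaningful            # |ΔΔG| < 5 kcal/mol: similar profiles
        _, meaningful2 = sk.ddg_comparison(-20.2, -29.3)
        assert meaningful2

    def test_empty_window_rejected(self, funnel_spec):
        frame = funnel_spec.bound_pose_frame()
        traj = sk.Trajectory(coords=frame[None], times_ps=[1.0])
        with pytest.raises(ValueError):
            sk.binding_energy_summary(traj, (5.0, 6.0), np.array([-1.0]))


class TestHbond:
    def test_constant_distance(self, funnel_structure):
        coords = funnel_structure.coords
        traj = sk.Trajectory(coords=np.repeat(coords[None], 3, 0),
                             times_ps=np.arange(1.0, 4))
        i, j = 0, 1
        d0 = np.linalg.norm(coords[i] - coords[j])
        series, mean, sd = sk.hbond_distance_series(traj, funnel_structure, i, j)
        assert np.allclose(series, d0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_two(self, funnel_structure):
        c = funnel_structure.coords.copy()
        frames = [c.copy(), c.copy()]
        frames[0][1] = frames[0][0] + [2.0, 0, 0]
        frames[1][1] = frames[1][0] + [3.0, 0, 0]
        traj = sk.Trajectory(coords=np.array(frames), times_ps=[1.0, 2.0])
        _, mean, _ = sk.hbond_distance_series(traj, funnel_structure, 0, 1)
        assert mean == pytest.approx(2.5)

    def test_matches_per_frame_oracle(self, funnel_structure):
        rg = np.random.default_rng(31)
        frames = funnel_structure.coords[None] + rg.normal(0, 1, (6, funnel_structure.n_atoms, 3))
        traj = sk.Trajectory(coords=frames, times_ps=np.arange(1.0, 7))
        series, _, _ = sk.hbond_distance_series(traj, funnel_structure, 2, 9)
        for f in range(6):
            assert series[f] == pytest.approx(
                np.linalg.norm(frames[f, 2] - frames[f, 9]), abs=1e-12)

    def test_missing_atom_rejected(self, funnel_structure):
        frame = funnel_structure.coords
        traj = sk.Trajectory(coords=frame[None], times_ps=[1.0])
        with pytest.raises(ValueError):
            sk.hbond_distance_series(traj, funnel_structure, 0, 10_000)
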