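"""Unbinding-trajectory analytics: RMSD series, detachment lags and
condition comparison."""

import numpy as np
import pytest

from mutadimer import synthdata
from mutadimer.errors import PDBFormatError
from mutadimer.structio import ResidueKey, write_pdb
from mutadimer.trajectory import (
    ATTACHED,
    PullingMeta,
    Trajectory,
    compare_conditions,
    detachment_lag,
    read_trajectory,
    residue_rmsd_series,
)
from conftest import random_rigid_transform


@pytest.fixture(scope="module")
def bound_pose(receptor_trp, ligand10, tag_key):
    ps, _ = synthdata.make_pose_ensemble(receptor_trp, ligand10, 1, 1.0,
                                         tag_key, seed=50)
    return ps.poses[0]


@pytest.fixture(scope="module")
def pulled_keys(bound_pose):
    s = bound_pose.structure
    return [k for k in s.residue_keys() if k.chain == "B"]


class TestReadTrajectory:
    def test_multi_model_read(self, tmp_path, bound_pose):
        frames = [bound_pose.structure.transformed(np.eye(3), [i, 0., 0.])
                  for i in range(5)]
        p = tmp_path / "traj.pdb"
        write_pdb(frames, p)
        t = read_trajectory(p, dt=0.1, pulling=PullingMeta("B", "A"))
        assert t.n_frames == 5

    def test_topology_drift_names_the_frame(self, tmp_path, bound_pose):
        s = bound_pose.structure
        broken = s._subset(np.arange(s.n_atoms - 1))
        p = tmp_path / "drift.pdb"
        with open(p, "w") as fh:
            for i, frame in enumerate([s, s, s, broken, s]):
                fh.write(f"MODEL     {i + 1}\n")
                tmp = tmp_path / "_frame.pdb"
                write_pdb(frame, tmp)
                for line in tmp.read_text().splitlines():
                    if line.startswith(("ATOM", "HETATM")):
                        fh.write(line + "\n")
                fh.write("ENDMDL\n")
        with pytest.raises(PDBFormatError, match="frame 3"):
            read_trajectory(p, dt=0.1)

    def test_invalid_dt_rejected(self, tmp_path, bound_pose):
        frames = [bound_pose.structure] * 3
        p = tmp_path / "t.pdb"
        write_pdb(frames, p)
        with pytest.raises(ValueError):
            read_trajectory(p, dt=0.0)


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self, bound_pose):
        traj, _ = synthdata.make_trajectory(bound_pose, {}, n_frames=5)
        series = residue_rmsd_series(traj)
        assert float(series.to_numpy().max()) < 1e-10

    def test_rigid_comotion_with_anchor_is_removed(self, bound_pose):
        s = bound_pose.structure
        rng = np.random.default_rng(2)
        frames = []
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            frames.append(s.transformed(R, t))
        traj = Trajectory(frames, dt=0.1, pulling=PullingMeta("B", "A"))
        series = residue_rmsd_series(traj)
        assert float(series.to_numpy().max()) < 1e-8

    def test_programmed_departure_speed_recovered(self, bound_pose,
                                                  pulled_keys):
        k = pulled_keys[0]
        schedule = {k: 10}
        traj, _ = synthdata.make_trajectory(bound_pose, schedule,
                                            n_frames=40, dt=0.1,
                                            pulling_speed=10.0)
        series = residue_rmsd_series(traj)
        v_dt = 1.0  # 10 A/ns * 0.1 ns
        for f in (15, 25, 39):
            expected = v_dt * (f - 10)
            assert series.loc[f, k] == pytest.approx(expected, rel=0.05)

    def test_series_invariant_under_global_rigid_transform(self,
                                                           bound_pose):
        schedule = {}
        traj, _ = synthdata.make_trajectory(bound_pose,
                                            {}, n_frames=4,
                                            noise_sigma=0.1, seed=7)
        R, t = random_rigid_transform(np.random.default_rng(12))
        moved = Trajectory([f.transformed(R, t) for f in traj.frames],
                           traj.dt, traj.pulling)
        a = residue_rmsd_series(traj).to_numpy()
        b = residue_rmsd_series(moved).to_numpy()
        assert np.allclose(a, b, atol=1e-8)


class TestDetachmentLag:
    def test_static_trajectory_all_attached(self, bound_pose):
        traj, _ = synthdata.make_trajectory(bound_pose, {}, n_frames=6)
        series = residue_rmsd_series(traj)
        res = detachment_lag(series)
        assert all(v == ATTACHED for v in res.per_residue_lag.values())

    def test_programmed_lags_recovered_noiselessly(self, bound_pose,
                                                   pulled_keys):
        schedule = {pulled_keys[0]: 5, pulled_keys[3]: 20,
                    pulled_keys[6]: 35}
        traj, truth = synthdata.make_trajectory(
            bound_pose, schedule, n_frames=50, dt=0.1, pulling_speed=10.0)
        series = residue_rmsd_series(traj)
        # threshold deliberately off the 1 A/frame lattice: no tie frames
        res = detachment_lag(series, threshold=2.5)
        for key, start in truth.items():
            expected = synthdata.expected_lag(start, 2.5, 0.1, 10.0)
            assert res.per_residue_lag[key] == expected
        unscheduled = [k for k in pulled_keys if k not in schedule]
        for key in unscheduled:
            assert res.per_residue_lag[key] == ATTACHED

    def test_raising_threshold_never_decreases_lag(self, bound_pose,
                                                   pulled_keys):
        schedule = {k: 5 + 3 * i for i, k in enumerate(pulled_keys[:5])}
        traj, _ = synthdata.make_trajectory(bound_pose, schedule,
                                            n_frames=50, noise_sigma=0.2,
                                            seed=3)
        series = residue_rmsd_series(traj)
        low = detachment_lag(series, threshold=2.0).per_residue_lag
        high = detachment_lag(series, threshold=5.0).per_residue_lag

        def rankof(v, n=50):
            return n + 1 if v == ATTACHED else v
        for key in low:
            assert rankof(high[key]) >= rankof(low[key])

    def test_group_curves_average_member_curves(self, bound_pose,
                                                pulled_keys):
        schedule = {pulled_keys[0]: 5, pulled_keys[1]: 10}
        traj, _ = synthdata.make_trajectory(bound_pose, schedule,
                                            n_frames=20)
        series = residue_rmsd_series(traj)
        groups = {"core": pulled_keys[:4], "rest": pulled_keys[4:]}
        res = detachment_lag(series, groups=groups)
        manual = series[pulled_keys[:4]].mean(axis=1)
        assert np.allclose(res.group_curves["core"].to_numpy(),
                           manual.to_numpy())


class TestCompareConditions:
    def test_identical_summaries_tie(self):
        ranking, f, p = compare_conditions({"a": [1.0, 2.0, 3.0],
                                            "b": [1.0, 2.0, 3.0]})
        assert p == pytest.approx(1.0)
        assert len(ranking) == 2

    def test_shifted_condition_ranked_weaker(self):
        rng = np.random.default_rng(4)
        base = rng.normal(3.0, 0.5, 8)
        ranking, f, p = compare_conditions(
            {"wt": list(base + 2.0), "mut": list(base)})
        assert ranking[0]["condition"] == "wt"
        assert ranking[0]["label"] == "weaker residual association"
        assert ranking[-1]["label"] == "stronger residual association"
        assert p < 0.05

    def test_replicate_minimum_enforced(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": [1.0], "b": [1.0, 2.0]})
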