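"""Pose-ensemble analytics: ingestion, contact clouds, externalization
scoring and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from mutadimer import synthdata
from mutadimer.dimers import (
    DimerPose,
    PoseSet,
    classify_externalization,
    com_cloud,
    load_poseset,
    residue_sasa_ensemble,
    two_group_test,
)
from mutadimer.errors import ManifestError
from mutadimer.structio import ResidueKey, write_pdb


@pytest.fixture(scope="module")
def pose_dir(tmp_path_factory, small_poseset):
    ps, _ = small_poseset
    d = tmp_path_factory.mktemp("poses")
    rows = []
    for pose in ps.poses[:3]:
        fname = f"pose_{pose.rank}.pdb"
        write_pdb(pose.structure, d / fname)
        rows.append({"file": fname, "rank": pose.rank,
                     "energy_score": pose.energy_score})
    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False)
    return d


class TestLoadPoseset:
    def test_loads_and_sorts_by_rank(self, pose_dir, tag_key):
        ps = load_poseset(pose_dir, pose_dir / "manifest.csv", "cond",
                          "A", tag_key)
        assert len(ps) == 3
        assert [p.rank for p in ps.poses] == sorted(p.rank for p in ps.poses)
        assert not ps.weighting_fallback

    def test_duplicate_rank_rejected(self, pose_dir, tag_key, tmp_path):
        m = pd.read_csv(pose_dir / "manifest.csv")
        m.loc[1, "rank"] = m.loc[0, "rank"]
        bad = tmp_path / "dup.csv"
        m.to_csv(bad, index=False)
        with pytest.raises(ManifestError):
            load_poseset(pose_dir, bad, "cond", "A", tag_key)

    def test_missing_energy_column_sets_fallback(self, pose_dir, tag_key,
                                                 tmp_path):
        m = pd.read_csv(pose_dir / "manifest.csv").drop(
            columns=["energy_score"])
        noe = tmp_path / "noe.csv"
        m.to_csv(noe, index=False)
        ps = load_poseset(pose_dir, noe, "cond", "A", tag_key)
        assert ps.weighting_fallback
        rep = classify_externalization(ps)
        assert rep.weighting == "rank"


class TestComCloud:
    def test_identical_poses_form_single_cluster(self, small_poseset):
        ps, _ = small_poseset
        clone = PoseSet([DimerPose(ps.poses[0].structure, r)
                         for r in range(1, 6)],
                        "clones", "A", ps.tagged_residue)
        grid, origin, clusters = com_cloud(clone, grid_spacing=2.0)
        assert len(clusters) == 1
        assert clusters[0]["members"] == 5

    def test_two_programmed_sites_recovered(self, receptor_trp, ligand10,
                                            tag_key):
        buried, _ = synthdata.make_pose_ensemble(
            receptor_trp, ligand10, 10, 1.0, tag_key, seed=5)
        exposed, _ = synthdata.make_pose_ensemble(
            receptor_trp, ligand10, 10, 0.0, tag_key, seed=5)
        ps = PoseSet(
            [DimerPose(p.structure, i + 1)
             for i, p in enumerate(buried.poses + exposed.poses)],
            "two-site", "A", tag_key)
        grid, origin, clusters = com_cloud(ps, grid_spacing=4.0)
        assert sum(c["members"] for c in clusters) == 20
        # the burial-side cluster centroid lies near the tag's outward axis
        rec = receptor_trp
        tag_pt = rec.coords[rec.atom_indices(tag_key)].mean(axis=0)
        best = min(np.linalg.norm(c["centroid"] - tag_pt) for c in clusters)
        assert best < 12.0

    def test_member_counts_conserved(self, small_poseset):
        ps, _ = small_poseset
        grid, origin, clusters = com_cloud(ps, grid_spacing=3.0)
        assert sum(c["members"] for c in clusters) == len(ps)


class TestClassifyExternalization:
    def test_never_buried_scores_one(self, receptor_trp, ligand10, tag_key):
        ps, _ = synthdata.make_pose_ensemble(receptor_trp, ligand10, 8,
                                             0.0, tag_key, seed=13)
        rep = classify_externalization(ps)
        assert rep.score == pytest.approx(1.0)

    def test_always_buried_scores_zero(self, receptor_trp, ligand10,
                                       tag_key):
        ps, _ = synthdata.make_pose_ensemble(receptor_trp, ligand10, 8,
                                             1.0, tag_key, seed=14)
        rep = classify_externalization(ps)
        assert rep.score == pytest.approx(0.0)

    def test_rank_weights_match_hand_computed_sum(self, receptor_trp,
                                                  ligand10, tag_key):
        ps, truth = synthdata.make_pose_ensemble(receptor_trp, ligand10,
                                                 10, 0.5, tag_key, seed=15)
        rep = classify_externalization(ps, weighting="rank")
        n = len(ps)
        weights = {r: (n - r + 1) / (n * (n + 1) / 2)
                   for r in range(1, n + 1)}
        external = dict(zip(truth["rank"], ~truth["intended_buried"]))
        expected = sum(weights[r] * bool(external[r]) for r in weights)
        assert rep.score == pytest.approx(expected, abs=1e-9)

    def test_weights_sum_to_one(self, small_poseset):
        ps, _ = small_poseset
        rep = classify_externalization(ps)
        assert rep.per_pose["weight"].sum() == pytest.approx(1.0)
        assert (rep.per_pose["weight"] >= 0).all()

    def test_mirror_score_complementarity(self, small_poseset):
        ps, _ = small_poseset
        rep = classify_externalization(ps)
        w = rep.per_pose["weight"].to_numpy()
        x = rep.per_pose["external"].to_numpy().astype(float)
        assert (w * (1 - x)).sum() == pytest.approx(1.0 - rep.score,
                                                    abs=1e-12)

    def test_sensitivity_thresholds_reported(self, small_poseset):
        ps, _ = small_poseset
        rep = classify_externalization(ps)
        assert set(rep.sensitivity) == {0.15, 0.25, 0.40}
        # looser burial criterion can only raise the externality score
        assert rep.sensitivity[0.40] >= rep.sensitivity[0.15]


class TestResidueSasaEnsemble:
    def test_identical_poses_identical_values(self, small_poseset):
        ps, _ = small_poseset
        clone = PoseSet([DimerPose(ps.poses[0].structure, r)
                         for r in range(1, 4)],
                        "clones", "A", ps.tagged_residue)
        vals = residue_sasa_ensemble(clone)
        assert len(vals) == 3
        assert max(vals) - min(vals) < 1e-9

    def test_buried_pose_lower_than_exposed_pose(self, receptor_trp,
                                                 ligand10, tag_key):
        buried, _ = synthdata.make_pose_ensemble(receptor_trp, ligand10, 3,
                                                 1.0, tag_key, seed=21)
        exposed, _ = synthdata.make_pose_ensemble(receptor_trp, ligand10, 3,
                                                  0.0, tag_key, seed=22)
        assert max(residue_sasa_ensemble(buried)) < \
            min(residue_sasa_ensemble(exposed))


class TestTwoGroupTest:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        t, p = two_group_test(a, list(a), kind="welch_t")
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_worked_welch_example(self):
        t, p = two_group_test([1, 2, 3], [2, 3, 4], kind="welch_t")
        # independent closed form: equal n, equal s^2=1 -> t = -1/sqrt(2/3),
        # df = 4, p from the regularized incomplete beta function
        se = math.sqrt(1.0 / 3 + 1.0 / 3)
        t_cf = (2.0 - 3.0) / se
        from scipy.special import betainc
        df = 4.0
        x = df / (df + t_cf ** 2)
        p_cf = betainc(df / 2, 0.5, x)
        assert t == pytest.approx(t_cf, abs=1e-12)
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(p_cf, abs=1e-12)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_three_identical_groups_anova(self):
        g = [1.0, 2.0, 3.0]
        f, p = two_group_test(g, list(g), list(g), kind="anova")
        assert f == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        t, p = two_group_test([2.0, 2.0], [2.0, 2.0], kind="welch_t")
        assert (t, p) == (0.0, 1.0)
        f, p = two_group_test([2.0, 2.0], [2.0, 2.0], kind="anova")
        assert (f, p) == (0.0, 1.0)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [1.0, 2.0], kind="welch_t")

    @pytest.mark.parametrize("kind", ["welch_t", "anova"])
    def test_matches_permutation_p(self, kind):
        rng = np.random.default_rng(8)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        _, p = two_group_test(a, b, kind=kind)
        pooled = np.concatenate([a, b])
        n_perm = 10_000
        count = 0
        obs = abs(a.mean() - b.mean())
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += abs(pooled[:10].mean() - pooled[10:].mean()) >= obs
        p_perm = count / n_perm
        mc_err = 3 * math.sqrt(p_perm * (1 - p_perm) / n_perm + 1e-6)
        assert abs(p - p_perm) < max(0.02, mc_err + 0.01)
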