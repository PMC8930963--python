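"""Group-by-time interaction inference: t maps, cluster formation,
permutation p values, trajectories and the sequence-specificity rule."""

import numpy as np
import pytest
from scipy import stats

from seqmotor.datatypes import ECMap, StageContrast, stage_contrasts
from seqmotor.errors import DesignError, InvalidArgumentError
from seqmotor.inference import (
    baseline_ec_test,
    classify_specificity,
    cluster_inference,
    delta_matrix,
    find_clusters,
    interaction_tmap,
    roi_trajectory,
    stage_report,
)
from seqmotor.reference_tables import (
    EXPECTED_DRIVING,
    EXPECTED_SPECIFIC,
    change_dict,
    regional_change_examples,
)

GRID = (10, 10, 10)


def _ecmap(values, mask=None):
    mask = np.ones(GRID, bool) if mask is None else mask
    v = np.zeros(GRID)
    v[mask] = values
    return ECMap(values=v, mask=mask, iterations=1, converged=True, eigenvalue_estimate=1.0)


def _random_maps(rng, n_per_group=8, days=("d1", "d5"), effect=0.0, effect_mask=None):
    """EC-like maps: uniform base + noise; optional planted LRN decrease."""
    maps, groups = {}, {}
    n_vox = int(np.prod(GRID))
    for g, prefix in (("LRN", "lrn"), ("SMP", "smp")):
        for i in range(n_per_group):
            s = f"{prefix}{i:02d}"
            groups[s] = g
            for day in days:
                base = 0.05 + rng.normal(0, 0.004, n_vox)
                if (g == "LRN" and len(days) > 1 and day == days[1]
                        and effect and effect_mask is not None):
                    base[effect_mask.reshape(-1)] -= effect
                maps[(s, day)] = _ecmap(base)
    return maps, groups


class TestStageContrasts:
    def test_eight_directional_contrasts(self):
        cs = stage_contrasts()
        assert len(cs) == 8
        assert {(c.name, c.day_pair, c.direction) for c in cs} == {
            ("fast", ("d1", "d2"), "decrease"), ("fast", ("d1", "d2"), "increase"),
            ("slow", ("d2", "d5"), "decrease"), ("slow", ("d2", "d5"), "increase"),
            ("overall", ("d1", "d5"), "decrease"), ("overall", ("d1", "d5"), "increase"),
            ("retention", ("d5", "d17"), "decrease"), ("retention", ("d5", "d17"), "increase"),
        }

    def test_invalid_direction_rejected(self):
        with pytest.raises(InvalidArgumentError):
            StageContrast("fast", ("d1", "d2"), "sideways")


class TestInteractionTmap:
    def test_direction_flip_negates_tmap(self):
        rng = np.random.default_rng(0)
        maps, groups = _random_maps(rng)
        dec = interaction_tmap(maps, groups, StageContrast("overall", ("d1", "d5"), "decrease"))
        inc = interaction_tmap(maps, groups, StageContrast("overall", ("d1", "d5"), "increase"))
        np.testing.assert_allclose(dec.t, -inc.t, atol=1e-12)
        assert dec.df == 2 * 8 - 2

    def test_null_tmap_follows_t_distribution(self):
        rng = np.random.default_rng(1)
        maps, groups = _random_maps(rng, n_per_group=10)
        tm = interaction_tmap(maps, groups, StageContrast("overall", ("d1", "d5"), "increase"))
        vals = tm.t[tm.mask]
        ks = stats.kstest(vals, stats.t(df=tm.df).cdf)
        assert ks.pvalue > 0.01

    def test_planted_effect_raises_region_t(self):
        rng = np.random.default_rng(2)
        effect_mask = np.zeros(GRID, bool)
        effect_mask[2:5, 2:5, 2:5] = True
        maps, groups = _random_maps(rng, effect=0.01, effect_mask=effect_mask)
        tm = interaction_tmap(maps, groups, StageContrast("overall", ("d1", "d5"), "decrease"))
        assert tm.t[effect_mask].mean() > tm.t[~effect_mask].mean() + 3

    def test_missing_session_listed(self):
        rng = np.random.default_rng(3)
        maps, groups = _random_maps(rng)
        del maps[("lrn00", "d5")]
        with pytest.raises(InvalidArgumentError, match="lrn00"):
            interaction_tmap(maps, groups, StageContrast("overall", ("d1", "d5"), "decrease"))


class TestFindClusters:
    def test_zero_map_no_clusters(self):
        _, recs = find_clusters(np.zeros(GRID), 3.0)
        assert recs == []

    def test_planted_cube_single_cluster(self):
        t3d = np.zeros(GRID)
        t3d[1:4, 2:4, 5:10] = 5.0  # 3*2*5 = 30 suprathreshold voxels
        labelled, recs = find_clusters(t3d, 3.0, connectivity=18)
        assert len(recs) == 1
        assert recs[0]["size"] == 30
        assert t3d[recs[0]["peak_coordinate"]] == 5.0

    def test_connectivity_matters_for_diagonal_voxels(self):
        t3d = np.zeros(GRID)
        t3d[2, 2, 2] = 5.0
        t3d[3, 3, 3] = 5.0  # corner-adjacent only
        _, recs6 = find_clusters(t3d, 3.0, connectivity=6)
        _, recs26 = find_clusters(t3d, 3.0, connectivity=26)
        assert len(recs6) == 2 and len(recs26) == 1

    def test_invalid_connectivity(self):
        with pytest.raises(InvalidArgumentError):
            find_clusters(np.zeros(GRID), 1.0, connectivity=10)


class TestClusterInference:
    def test_planted_effect_detected(self):
        rng = np.random.default_rng(4)
        effect_mask = np.zeros(GRID, bool)
        effect_mask[2:6, 2:6, 2:6] = True
        maps, groups = _random_maps(rng, effect=0.012, effect_mask=effect_mask)
        deltas, labels, mask, _ = delta_matrix(maps, groups, ("d1", "d5"))
        cls = cluster_inference(deltas, labels, mask, direction="decrease",
                                n_perm=200, seed=0)
        assert len(cls) >= 1
        best = max(cls, key=lambda c: c.size)
        dice = 2 * (best.mask & effect_mask).sum() / (best.mask.sum() + effect_mask.sum())
        assert dice > 0.5

    def test_no_suprathreshold_returns_empty(self):
        rng = np.random.default_rng(5)
        maps, groups = _random_maps(rng, n_per_group=4)
        deltas, labels, mask, _ = delta_matrix(maps, groups, ("d1", "d5"))
        # identical group distributions, tiny n: nothing should pass, and
        # an empty result must not raise
        cls = cluster_inference(deltas, labels, mask, direction="decrease",
                                n_perm=150, seed=0)
        assert isinstance(cls, list)

    def test_direction_cluster_sets_disjoint(self):
        rng = np.random.default_rng(6)
        effect_mask = np.zeros(GRID, bool)
        effect_mask[2:6, 2:6, 2:6] = True
        maps, groups = _random_maps(rng, effect=0.012, effect_mask=effect_mask)
        deltas, labels, mask, _ = delta_matrix(maps, groups, ("d1", "d5"))
        dec = cluster_inference(deltas, labels, mask, direction="decrease",
                                n_perm=150, seed=0, keep_all=True)
        inc = cluster_inference(deltas, labels, mask, direction="increase",
                                n_perm=150, seed=0, keep_all=True)
        dec_vox = set(map(tuple, np.argwhere(sum(c.mask for c in dec) > 0))) if dec else set()
        inc_vox = set(map(tuple, np.argwhere(sum(c.mask for c in inc) > 0))) if inc else set()
        assert not (dec_vox & inc_vox)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(7)
        maps, groups = _random_maps(rng)
        only_lrn = {k: v for k, v in maps.items() if k[0].startswith("lrn")}
        with pytest.raises(DesignError):
            delta_matrix(only_lrn, groups, ("d1", "d5"))


class TestBaselineEcTest:
    def test_planted_offset_detected_and_null_clean(self):
        rng = np.random.default_rng(8)
        maps, groups = _random_maps(rng, n_per_group=8, days=("d0",))
        tm, cls = baseline_ec_test(maps, groups, "d0", n_perm=150, seed=0)
        assert cls == []  # no planted difference at baseline
        region = np.zeros(GRID, bool)
        region[4:8, 4:8, 4:8] = True
        for (s, d) in maps:
            if s.startswith("lrn"):
                maps[(s, d)].values[region] += 0.012
        _, cls2 = baseline_ec_test(maps, groups, "d0", n_perm=150, seed=0)
        assert len(cls2) >= 1
        best = max(cls2, key=lambda c: c.size)
        dice = 2 * (best.mask & region).sum() / (best.mask.sum() + region.sum())
        assert dice > 0.5


class TestRoiTrajectoryAndSpecificity:
    def test_identical_subjects_zero_sem(self):
        maps, groups = {}, {}
        for g, prefix in (("LRN", "lrn"), ("SMP", "smp")):
            for i in range(4):
                s = f"{prefix}{i}"
                groups[s] = g
                for day in ("d1", "d5"):
                    maps[(s, day)] = _ecmap(np.full(int(np.prod(GRID)), 0.05))
        roi = np.zeros(GRID, bool)
        roi[3:5, 3:5, 3:5] = True
        traj = roi_trajectory(maps, roi, groups, ["d1", "d5"], ("d1", "d5"))
        for g in ("LRN", "SMP"):
            assert traj.change[g]["sem"] == 0.0
            lo, hi = traj.change[g]["ci95"]
            assert lo == hi == traj.change[g]["mean"]

    def test_single_subject_group_flagged(self):
        maps, groups = {}, {}
        rng = np.random.default_rng(9)
        for g, prefix, n in (("LRN", "lrn", 1), ("SMP", "smp", 3)):
            for i in range(n):
                s = f"{prefix}{i}"
                groups[s] = g
                for day in ("d1", "d5"):
                    maps[(s, day)] = _ecmap(0.05 + rng.normal(0, 0.001, int(np.prod(GRID))))
        roi = np.zeros(GRID, bool)
        roi[3:5, 3:5, 3:5] = True
        traj = roi_trajectory(maps, roi, groups, ["d1", "d5"], ("d1", "d5"))
        assert np.isnan(traj.change["LRN"]["sem"])

    def test_empty_roi_rejected(self):
        rng = np.random.default_rng(10)
        maps, groups = _random_maps(rng, n_per_group=2)
        with pytest.raises(InvalidArgumentError):
            roi_trajectory(maps, np.zeros(GRID, bool), groups, ["d1", "d5"], ("d1", "d5"))


class TestClassifySpecificity:
    def test_reproduces_published_regional_assignments(self):
        """The classifier must reproduce the worked-example labels for all
        8 regional change rows (only the right SMA, overall learning, is a
        sequence-specific, LRN-driven effect)."""
        examples = regional_change_examples()
        assert len(examples) == 8
        for _, row in examples.iterrows():
            verdict = classify_specificity(change_dict(row))
            key = (row["stage"], row["region"])
            assert verdict.driving_group == EXPECTED_DRIVING[key], key
            assert verdict.sequence_specific == EXPECTED_SPECIFIC[key], key

    def test_lrn_driven_with_quiet_smp_is_specific(self):
        v = classify_specificity({
            "LRN": dict(mean=-0.10, sem=0.02, ci95=(-0.14, -0.06), n=20),
            "SMP": dict(mean=0.03, sem=0.02, ci95=(-0.02, 0.08), n=20),
        })
        assert v.driving_group == "LRN" and v.sequence_specific

    def test_smp_driven_not_specific(self):
        v = classify_specificity({
            "LRN": dict(mean=0.02, sem=0.03, ci95=(-0.04, 0.08), n=20),
            "SMP": dict(mean=-0.13, sem=0.02, ci95=(-0.17, -0.10), n=20),
        })
        assert v.driving_group == "SMP" and not v.sequence_specific

    def test_neither_group_driving(self):
        v = classify_specificity({
            "LRN": dict(mean=0.0, sem=0.02, ci95=(-0.04, 0.04), n=20),
            "SMP": dict(mean=0.0, sem=0.02, ci95=(-0.04, 0.04), n=20),
        })
        assert v.driving_group == "none" and not v.sequence_specific

    def test_tie_break_by_magnitude(self):
        v = classify_specificity({
            "LRN": dict(mean=0.06, sem=0.02, ci95=(0.02, 0.11), n=20),
            "SMP": dict(mean=-0.12, sem=0.03, ci95=(-0.19, -0.06), n=20),
        })
        assert v.driving_group == "SMP"
        assert "tie_break" in v.rationale

    def test_missing_group_rejected(self):
        with pytest.raises(DesignError):
            classify_specificity({"LRN": dict(mean=0, sem=0, ci95=(0, 0), n=2)})


class TestStageReport:
    def test_empty_analyses_give_wellformed_tables(self):
        rep = stage_report([])
        assert list(rep["clusters"].columns)[:3] == ["stage", "day_pair", "direction"]
        assert rep["summary"].empty and rep["clusters"].empty
        assert rep["json"]["clusters"] == []

    def test_json_round_trip(self):
        import json

        rng = np.random.default_rng(11)
        effect_mask = np.zeros(GRID, bool)
        effect_mask[2:6, 2:6, 2:6] = True
        maps, groups = _random_maps(rng, effect=0.012, effect_mask=effect_mask)
        from seqmotor.inference import interaction_analysis

        res = interaction_analysis(
            maps, groups, StageContrast("overall", ("d1", "d5"), "decrease"),
            n_perm=150, seed=0,
        )
        rep = stage_report([res])
        payload = json.loads(json.dumps(rep["json"]))
        assert payload["clusters"] == rep["json"]["clusters"]
        assert len(rep["summary"]) == 2 * len(res["clusters"])
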