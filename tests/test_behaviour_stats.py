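"""Behavioural statistics: baseline Welch t, mixed ANOVA with sphericity
handling, Tukey consecutive-day post hocs — cross-validated against
independent reference implementations (pingouin, scipy)."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from seqmotor.behaviour_stats import (
    _pivot,
    baseline_ttest,
    gg_epsilon,
    hf_epsilon,
    mauchly_test,
    mixed_anova,
    rm_anova,
    trace_type_table,
    tukey_consecutive,
)
from seqmotor.errors import DataCompletenessError

DAYS = ["d1", "d2", "d3", "d4", "d5", "d17"]


def _long_table(seed, n_units=8, learning=("LRN",)):
    rng = np.random.default_rng(seed)
    rows = []
    for gname in ["LRN", "LRN_SMP", "SMP"]:
        for u in range(n_units):
            unit = f"{gname}:{u}"
            base = rng.normal(200 - 40 * (gname == "SMP"), 30)
            for j, day in enumerate(DAYS):
                drop = 12 * j if gname in learning else 0.0
                rows.append(
                    dict(unit=unit, between=gname, day=day,
                         value=base - drop + rng.normal(0, 15))
                )
    return pd.DataFrame(rows)


def _scored_from_long(long):
    """Rewrap a unit x day long table as a scored-cohort-like table."""
    out = long.copy()
    out["subject"] = out["unit"].str.replace(":", "_")
    out["group"] = np.where(out["between"] == "SMP", "SMP", "LRN")
    out["condition"] = np.where(out["between"] == "LRN", "LRN", "SMP")
    # LRN_SMP units masquerade as the LRN group's SMP trials
    out.loc[out["between"] == "LRN_SMP", "subject"] = (
        out.loc[out["between"] == "LRN_SMP", "unit"].str.split(":").str[1].radd("LRN_")
    )
    out["block"] = 1
    out["trial"] = 1
    out["syn_ms"] = out["value"]
    out["rmse"] = out["value"] / 10.0
    out["peak_corr"] = 0.9
    out["degenerate"] = False
    return out


class TestBaselineTTest:
    def _scored_first_block(self, a_vals, b_vals):
        rows = []
        for g, vals in (("LRN", a_vals), ("SMP", b_vals)):
            for i, v in enumerate(vals):
                for trial in (1, 2, 3):
                    rows.append(
                        dict(subject=f"{g.lower()}{i}", group=g, day="d1", block=1,
                             trial=trial, condition="SMP", syn_ms=v, rmse=v / 2,
                             peak_corr=0.9, degenerate=False)
                    )
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        tab = self._scored_first_block([100, 110, 120], [100, 110, 120])
        res = baseline_ttest(tab)
        assert res["syn_ms"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["syn_ms"]["p"] == pytest.approx(1.0)

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(100, 20, 12), rng.normal(90, 30, 12)
        tab = self._scored_first_block(a, b)
        res = baseline_ttest(tab)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert res["syn_ms"]["t"] == pytest.approx(t_ref, abs=1e-10)
        assert res["syn_ms"]["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_missing_first_block_raises(self):
        tab = self._scored_first_block([1, 2, 3], [1, 2, 3])
        with pytest.raises(DataCompletenessError):
            baseline_ttest(tab[tab["group"] == "LRN"])


class TestMixedAnova:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_pingouin(self, seed):
        long = _long_table(seed)
        mine = {r.effect: r for r in mixed_anova(long)}
        ref = pg.mixed_anova(
            data=long, dv="value", between="between", within="day",
            subject="unit", correction=True,
        ).set_index("Source")
        assert mine["group"].F == pytest.approx(ref.at["between", "F"], abs=1e-8)
        assert mine["day"].F == pytest.approx(ref.at["day", "F"], abs=1e-8)
        assert mine["group x day"].F == pytest.approx(ref.at["Interaction", "F"], abs=1e-8)
        # uncorrected df recoverable from the epsilon-scaled df
        eps = mine["day"].epsilon if mine["day"].correction == "greenhouse-geisser" else None
        if eps is not None:
            assert mine["day"].df_num / eps == pytest.approx(ref.at["day", "DF1"], abs=1e-6)
        assert mine["day"].epsilon == pytest.approx(ref.at["day", "eps"], abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 4])
    def test_epsilon_and_mauchly_match_pingouin(self, seed):
        long = _long_table(seed)
        piv, _ = _pivot(long)
        cov = np.cov(piv.to_numpy(), rowvar=False)
        assert gg_epsilon(cov) == pytest.approx(pg.epsilon(piv, correction="gg"), abs=1e-8)
        assert hf_epsilon(gg_epsilon(cov), *piv.shape) == pytest.approx(
            pg.epsilon(piv, correction="hf"), abs=1e-8
        )
        sph = pg.sphericity(piv)
        w, chi2, p = mauchly_test(piv)
        assert w == pytest.approx(sph.W, abs=1e-8)
        assert p == pytest.approx(sph.pval, abs=1e-8)

    def test_all_cells_equal_gives_zero_f(self):
        rows = [
            dict(unit=f"{g}:{u}", between=g, day=d, value=42.0)
            for g in ("LRN", "SMP") for u in range(5) for d in DAYS
        ]
        res = mixed_anova(pd.DataFrame(rows))
        for r in res:
            assert np.isnan(r.F) or r.F == pytest.approx(0.0, abs=1e-12)

    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(0)
        n, k = 4000, 6
        subj = rng.normal(0, 3, n)[:, None]
        data = subj + rng.normal(0, 1, (n, k))
        eps = gg_epsilon(np.cov(data, rowvar=False))
        assert eps == pytest.approx(1.0, abs=0.01)


class TestTukeyConsecutive:
    def test_matches_scipy_tukey(self):
        long = _long_table(7)
        scored = _scored_from_long(long)
        tk = tukey_consecutive(scored, dv="syn_ms")
        for trace in ("LRN", "SMP"):
            sub = long[long.between == trace]
            piv = sub.pivot_table(index="unit", columns="day", values="value")[DAYS]
            ref = stats.tukey_hsd(*[piv[c].to_numpy() for c in piv.columns])
            mine = tk[tk.trace == trace]
            for _, row in mine.iterrows():
                i, j = DAYS.index(row.day_a), DAYS.index(row.day_b)
                assert row.p_tukey == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_reports_consecutive_pairs_only(self):
        tk = tukey_consecutive(_scored_from_long(_long_table(7)), dv="syn_ms")
        pairs = set(zip(tk.day_a, tk.day_b))
        assert pairs == {("d1", "d2"), ("d2", "d3"), ("d3", "d4"), ("d4", "d5"), ("d5", "d17")}

    def test_planted_fast_learning_detected_in_lrn_only(self):
        rng = np.random.default_rng(8)
        rows = []
        for gname in ("LRN", "LRN_SMP", "SMP"):
            for u in range(10):
                unit = f"{gname}:{u}"
                for j, day in enumerate(DAYS):
                    val = 200.0 + rng.normal(0, 10)
                    if gname == "LRN" and day != "d1":
                        val -= 120.0  # strong d1 -> d2 improvement, then flat
                    rows.append(dict(unit=unit, between=gname, day=day, value=val))
        scored = _scored_from_long(pd.DataFrame(rows))
        tk = tukey_consecutive(scored, dv="syn_ms")
        lrn_12 = tk[(tk.trace == "LRN") & (tk.day_a == "d1")].iloc[0]
        assert lrn_12.significant
        assert not tk[tk.trace == "SMP"]["significant"].any()

    def test_all_days_equal_nothing_significant(self):
        rows = [
            dict(unit=f"{g}:{u}", between=g, day=d, value=100.0 + u)
            for g in ("LRN", "SMP") for u in range(6) for d in DAYS
        ]
        tk = tukey_consecutive(_scored_from_long(pd.DataFrame(rows)), dv="syn_ms")
        assert not tk["significant"].any()


class TestRmAnovaOnCohort:
    def test_three_level_trace_coding(self, small_cohort):
        from seqmotor.scoring import score_cohort

        traces, meta, _ = small_cohort
        scored = score_cohort(traces, meta)
        long = trace_type_table(scored, dv="syn_ms")
        assert set(long["between"]) == {"LRN", "LRN_SMP", "SMP"}
        # learning-group subjects contribute two units each
        n_lrn_subj = scored[scored.group == "LRN"]["subject"].nunique()
        assert long["unit"].nunique() == n_lrn_subj * 2 + scored[
            scored.group == "SMP"]["subject"].nunique()
        res = rm_anova(scored, dv="syn_ms")
        assert {r.effect for r in res} == {"group", "day", "group x day"}
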