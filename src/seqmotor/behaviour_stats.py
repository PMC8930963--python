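"""Group-level statistics on scored pinch-force performance.

The analysis follows the study design for a two-group longitudinal motor
learning experiment:

* a Welch two-sample t test on the first block of the simple (SMP)
  sequence on day 1 verifies that groups start out equivalent;
* a mixed-design ANOVA with a within factor *day* (d1..d5, d17) and a
  between factor over *performance traces* tests learning over time. By
  default the between factor has three levels — the learning group's
  complex-sequence trials (LRN), the learning group's simple-sequence
  trials (LRN_SMP) and the control group's simple-sequence trials (SMP) —
  because the learning group produces two distinct performance traces per
  day. A two-level group coding is available via ``coding="group"``.
* sphericity is assessed with Mauchly's test; when it rejects, degrees of
  freedom are corrected with Greenhouse–Geisser if the GG epsilon is below
  0.75 and Huynh–Feldt otherwise;
* Tukey HSD post hocs compare consecutive days within each performance
  trace.

The ANOVA/Tukey machinery is implemented from the textbook balanced-design
sums of squares; the test-suite cross-checks it against independent
reference implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnovaResult
from .errors import DataCompletenessError, DesignError, InvalidArgumentError
from .scoring import day_means

__all__ = [
    "baseline_ttest",
    "trace_type_table",
    "mixed_anova",
    "rm_anova",
    "gg_epsilon",
    "hf_epsilon",
    "mauchly_test",
    "tukey_consecutive",
]

DAY_ORDER = ["d1", "d2", "d3", "d4", "d5", "d17"]


def baseline_ttest(
    scored: pd.DataFrame, metrics: tuple[str, ...] = ("syn_ms", "rmse")
) -> dict[str, dict]:
    """Welch two-sample t test on the day-1 first-block SMP averages.

    Each subject contributes the mean of their first three simple-sequence
    trials on the first training day; groups are compared per metric.
    """
    ok = ~scored["degenerate"] if "degenerate" in scored.columns else True
    first = scored[
        (scored["day"] == "d1")
        & (scored["block"] == 1)
        & (scored["condition"] == "SMP")
        & ok
    ]
    if first.empty:
        raise DataCompletenessError("no day-1 first-block SMP trials in table")
    per_subj = first.groupby(["subject", "group"], sort=False)[list(metrics)].mean().reset_index()
    out = {}
    for metric in metrics:
        a = per_subj.loc[per_subj["group"] == "LRN", metric].to_numpy()
        b = per_subj.loc[per_subj["group"] == "SMP", metric].to_numpy()
        if a.size == 0 or b.size == 0:
            raise DataCompletenessError("both groups need day-1 first-block SMP data")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        # Welch-Satterthwaite degrees of freedom
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb == 0:
            t, p, df = 0.0, 1.0, a.size + b.size - 2.0
        else:
            df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        out[metric] = {"t": float(t), "df": float(df), "p": float(p)}
    return out


def trace_type_table(
    scored: pd.DataFrame, dv: str = "syn_ms", coding: str = "trace_type"
) -> pd.DataFrame:
    """Long-format unit x day table for the mixed ANOVA.

    With the default three-level coding, each learning-group subject
    contributes two observational units (their LRN trace and their SMP
    trace); control subjects contribute one.
    """
    if "excluded" in scored.columns:
        scored = scored[~scored["excluded"]]
    dm = day_means(scored)
    if coding == "trace_type":
        dm = dm.copy()
        dm["trace_type"] = np.where(
            dm["group"] == "SMP",
            "SMP",
            np.where(dm["condition"] == "LRN", "LRN", "LRN_SMP"),
        )
        dm["unit"] = dm["subject"] + ":" + dm["trace_type"]
        return dm[["unit", "trace_type", "day", dv]].rename(
            columns={"trace_type": "between", dv: "value"}
        )
    if coding == "group":
        pooled = (
            dm.groupby(["subject", "group", "day"], sort=False)[dv].mean().reset_index()
        )
        pooled["unit"] = pooled["subject"]
        return pooled[["unit", "group", "day", dv]].rename(
            columns={"group": "between", dv: "value"}
        )
    raise InvalidArgumentError("coding must be 'trace_type' or 'group'")


def _pivot(long: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    days = [d for d in DAY_ORDER if d in set(long["day"])]
    piv = long.pivot_table(index="unit", columns="day", values="value")[days]
    if piv.isna().any().any():
        dropped = piv.index[piv.isna().any(axis=1)].tolist()
        import warnings

        warnings.warn(f"dropping units with missing days: {dropped}", stacklevel=3)
        piv = piv.dropna()
    between = long.drop_duplicates("unit").set_index("unit")["between"].loc[piv.index]
    return piv, between


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the day-by-day covariance matrix."""
    k = cov.shape[0]
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    num = k**2 * (mean_diag - mean_all) ** 2
    row_means = cov.mean(axis=1)
    den = (k - 1) * (
        (cov**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2
    )
    if den == 0:
        return 1.0  # constant data: sphericity trivially holds
    return float(num / den)


def hf_epsilon(eps_gg: float, n_units: int, k: int) -> float:
    """Huynh–Feldt epsilon (capped at 1)."""
    num = n_units * (k - 1) * eps_gg - 2
    den = (k - 1) * (n_units - 1 - (k - 1) * eps_gg)
    return float(min(1.0, num / den))


def mauchly_test(piv: pd.DataFrame) -> tuple[float, float, float]:
    """Mauchly's sphericity test on a units x days pivot.

    Returns (W, chi2, p).
    """
    data = piv.to_numpy(dtype=float)
    n, k = data.shape
    # orthonormal contrasts of the k within levels
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    s = np.cov(data, rowvar=False)
    a = c.T @ s @ c
    eig = np.linalg.eigvalsh(a)
    eig = np.clip(eig, 1e-300, None)
    d = k - 1
    w = float(np.exp(np.sum(np.log(eig)) - d * np.log(np.mean(eig))))
    f_corr = 1 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(w)
    ddof = d * (d + 1) // 2 - 1
    # second-order Box correction to the chi2 approximation
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f_corr) ** 2)
    )
    p1 = stats.chi2.sf(chi2, ddof)
    p2 = stats.chi2.sf(chi2, ddof + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w, float(chi2), p


def rm_anova_oneway(piv: pd.DataFrame) -> dict:
    """One-way repeated measures ANOVA on a units x days pivot (helper)."""
    data = piv.to_numpy(dtype=float)
    n, k = data.shape
    grand = data.mean()
    ss_day = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_units = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_day - ss_units
    return dict(ss_day=ss_day, ss_units=ss_units, ss_total=ss_total, ss_err=ss_err, n=n, k=k)


def mixed_anova(
    long: pd.DataFrame, alpha_sphericity: float = 0.05
) -> list[AnovaResult]:
    """Balanced mixed-design ANOVA: within factor day, between factor as
    provided in the ``between`` column of the long table.

    Sphericity-corrected day and interaction rows are produced when
    Mauchly's test rejects: Greenhouse–Geisser if the GG epsilon is below
    0.75, Huynh–Feldt otherwise.
    """
    piv, between = _pivot(long)
    data = piv.to_numpy(dtype=float)
    n, k = data.shape
    groups = between.unique()
    g = len(groups)
    if g < 2 or k < 2:
        raise DesignError("need at least 2 between levels and 2 days")

    grand = data.mean()
    ss_total = ((data - grand) ** 2).sum()
    ss_day = n * ((data.mean(axis=0) - grand) ** 2).sum()
    unit_means = data.mean(axis=1)
    group_sizes = {gr: int((between == gr).sum()) for gr in groups}
    ss_betw = k * sum(
        group_sizes[gr] * (unit_means[(between == gr).to_numpy()].mean() - grand) ** 2
        for gr in groups
    )
    # cell means (group x day)
    ss_cells = 0.0
    for gr in groups:
        sub = data[(between == gr).to_numpy()]
        ss_cells += sub.shape[0] * ((sub.mean(axis=0) - grand) ** 2).sum()
    ss_inter = ss_cells - ss_day - ss_betw
    ss_subj_within = k * sum(
        ((unit_means[(between == gr).to_numpy()] - unit_means[(between == gr).to_numpy()].mean()) ** 2).sum()
        for gr in groups
    )
    ss_err_within = ss_total - ss_cells - ss_subj_within

    df_betw, df_resbetw = g - 1, n - g
    df_day, df_inter = k - 1, (g - 1) * (k - 1)
    df_reswith = (k - 1) * (n - g)

    def f_stat(ss_eff, df_eff, ss_err, df_err):
        if ss_eff <= 0:
            return 0.0  # includes the degenerate all-cells-equal case
        return (ss_eff / df_eff) / (ss_err / df_err)

    f_betw = f_stat(ss_betw, df_betw, ss_subj_within, df_resbetw)
    f_day = f_stat(ss_day, df_day, ss_err_within, df_reswith)
    f_inter = f_stat(ss_inter, df_inter, ss_err_within, df_reswith)

    w, chi2, p_mauchly = mauchly_test(piv)
    eps_gg = gg_epsilon(np.cov(data, rowvar=False))
    eps_hf = hf_epsilon(eps_gg, n, k)
    needs_correction = p_mauchly < alpha_sphericity
    if needs_correction:
        correction = "greenhouse-geisser" if eps_gg < 0.75 else "huynh-feldt"
        eps = eps_gg if correction == "greenhouse-geisser" else eps_hf
    else:
        correction, eps = "none", 1.0

    def row(effect, F, df1, df2, ss_eff, ss_err, corrected):
        e = eps if corrected else 1.0
        return AnovaResult(
            effect=effect,
            F=float(F),
            df_num=float(df1 * e),
            df_den=float(df2 * e),
            p=float(stats.f.sf(F, df1 * e, df2 * e)),
            eta_sq=float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err > 0 else 0.0,
            epsilon=eps_gg,
            correction="none" if not corrected else correction,
            mauchly_W=w,
            mauchly_p=p_mauchly,
        )

    results = [
        row("group", f_betw, df_betw, df_resbetw, ss_betw, ss_subj_within, False),
        row("day", f_day, df_day, df_reswith, ss_day, ss_err_within, needs_correction),
        row(
            "group x day",
            f_inter,
            df_inter,
            df_reswith,
            ss_inter,
            ss_err_within,
            needs_correction,
        ),
    ]
    return results


def rm_anova(
    scored: pd.DataFrame, dv: str = "syn_ms", coding: str = "trace_type"
) -> list[AnovaResult]:
    """Mixed ANOVA on a scored cohort table (convenience wrapper)."""
    return mixed_anova(trace_type_table(scored, dv=dv, coding=coding))


def tukey_consecutive(
    scored: pd.DataFrame, dv: str = "syn_ms", coding: str = "trace_type"
) -> pd.DataFrame:
    """Tukey HSD across days within each performance trace, reported for
    the consecutive-day pairs (d1-d2, d2-d3, d3-d4, d4-d5, d5-d17).

    Day samples are the per-unit day means; the studentized-range p uses
    the pooled within-day mean square.
    """
    long = trace_type_table(scored, dv=dv, coding=coding)
    rows = []
    for trace, sub in long.groupby("between"):
        piv, _ = _pivot(sub.assign(between=trace))
        days = list(piv.columns)
        data = piv.to_numpy(dtype=float)
        n, k = data.shape
        ms_w = data.var(axis=0, ddof=1).sum() * (n - 1) / (k * (n - 1))
        df_w = k * (n - 1)
        means = data.mean(axis=0)
        for a, b in zip(days[:-1], days[1:]):
            ia, ib = days.index(a), days.index(b)
            diff = means[ia] - means[ib]
            se = np.sqrt(ms_w / n)
            q = abs(diff) / se if se > 0 else 0.0
            p = float(stats.studentized_range.sf(q, k, df_w)) if se > 0 else 1.0
            rows.append(
                dict(
                    trace=trace,
                    day_a=a,
                    day_b=b,
                    mean_diff=float(diff),
                    q=float(q),
                    p_tukey=min(1.0, p),
                    significant=p < 0.05,
                )
            )
    return pd.DataFrame(rows)
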