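"""Trial-level performance scoring for the sequential pinch force task.

Two metrics quantify how well the participant's force curve (FOR) tracks
the reference (REF):

* **SYN** — temporal synchronization: the signed lag (ms) at which the
  Pearson cross-correlation between REF and FOR is maximal. 0 ms is perfect
  timing; positive values mean FOR lags behind REF.
* **lag-aligned RMSE** — the root mean squared force deviation between REF
  and FOR after shifting FOR by the estimated lag, i.e. the spatial
  tracking error with timing removed.

Correlation is evaluated at integer sample lags only (12.5 ms granularity
at 80 Hz); no sub-sample interpolation is attempted. At each candidate lag
only the overlapping support of the two traces enters the Pearson
correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ForceTrace
from .errors import DegenerateTrialError, DesignError, InvalidArgumentError

__all__ = [
    "compute_syn",
    "compute_rmse",
    "score_trial",
    "score_cohort",
    "block_means",
    "day_means",
    "exclude_outliers",
]


def _check_pair(ref: ForceTrace, force: ForceTrace):
    if ref.fs != force.fs:
        raise InvalidArgumentError("REF and FOR must share the sampling rate")
    if ref.n_samples != force.n_samples:
        raise InvalidArgumentError("REF and FOR must share the trial length")


def compute_syn(
    ref: ForceTrace, force: ForceTrace, max_lag_s: float = 3.0
) -> tuple[float, float]:
    """Estimate the synchronization lag (SYN, ms) and its peak correlation.

    The normalized cross-correlation is evaluated at every integer sample
    lag within ``[-max_lag_s, +max_lag_s]``; ties are broken toward the
    smaller absolute lag, then toward the positive lag.
    """
    _check_pair(ref, force)
    if not max_lag_s < ref.duration / 2:
        raise InvalidArgumentError("max_lag_s must be below half the trial duration")
    if np.ptp(ref.samples) == 0 or np.ptp(force.samples) == 0:
        raise DegenerateTrialError("zero-variance trace; trial cannot be scored")

    max_k = int(round(max_lag_s * ref.fs))
    x, y = ref.samples, force.samples
    lags = np.arange(-max_k, max_k + 1)
    corrs = np.full(lags.size, -np.inf)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = x[: x.size - k] if k else x, y[k:]
        else:
            a, b = x[-k:], y[: y.size + k]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        corrs[i] = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
    if not np.isfinite(corrs).any():
        raise DegenerateTrialError("no candidate lag has finite correlation")

    best = corrs.max()
    # tie-break: smallest |lag|, then positive sign
    candidates = lags[np.isclose(corrs, best, rtol=0, atol=1e-12)]
    order = np.lexsort((-np.sign(candidates), np.abs(candidates)))
    k_best = int(candidates[order[0]])
    return k_best / ref.fs * 1000.0, float(best)


def compute_rmse(ref: ForceTrace, force: ForceTrace, syn_ms: float) -> float:
    """Lag-aligned root mean squared error between REF and FOR.

    FOR is shifted back by the estimated lag; the RMSE is taken over the
    overlapping support only.
    """
    _check_pair(ref, force)
    k = int(round(syn_ms / 1000.0 * ref.fs))
    n = ref.n_samples
    if k >= 0:
        a, b = ref.samples[: n - k] if k else ref.samples, force.samples[k:]
    else:
        a, b = ref.samples[-k:], force.samples[: n + k]
    if a.size < 0.5 * n:
        raise DegenerateTrialError(
            f"lag {syn_ms} ms leaves only {a.size}/{n} overlapping samples"
        )
    return float(np.sqrt(np.mean((a - b) ** 2)))


def score_trial(ref: ForceTrace, force: ForceTrace, max_lag_s: float = 3.0):
    from .datatypes import TrialScore

    syn, peak = compute_syn(ref, force, max_lag_s)
    rmse = compute_rmse(ref, force, syn)
    return TrialScore(syn_ms=syn, rmse=rmse, peak_corr=peak)


def score_cohort(
    traces: dict[str, tuple[ForceTrace, ForceTrace]],
    metadata: pd.DataFrame,
    max_lag_s: float = 3.0,
) -> pd.DataFrame:
    """Score every trial of a cohort.

    ``metadata`` must have columns subject, group, day, block, trial,
    condition and trace_key (resolving into ``traces``). Returns the table
    with syn_ms, rmse, peak_corr and a ``degenerate`` flag appended;
    degenerate trials carry NaN scores.
    """
    required = {"subject", "group", "day", "block", "trial", "condition", "trace_key"}
    missing = required - set(metadata.columns)
    if missing:
        raise InvalidArgumentError(f"metadata is missing columns: {sorted(missing)}")
    out = metadata.copy()
    syns, rmses, peaks, degen = [], [], [], []
    for key in out["trace_key"]:
        if key not in traces:
            raise FileNotFoundError(f"trace {key!r} not found for metadata row")
        ref, force = traces[key]
        try:
            s = score_trial(ref, force, max_lag_s)
            syns.append(s.syn_ms)
            rmses.append(s.rmse)
            peaks.append(s.peak_corr)
            degen.append(False)
        except DegenerateTrialError:
            syns.append(np.nan)
            rmses.append(np.nan)
            peaks.append(np.nan)
            degen.append(True)
    out["syn_ms"] = syns
    out["rmse"] = rmses
    out["peak_corr"] = peaks
    out["degenerate"] = degen
    return out


def block_means(scored: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition x day x block means (degenerate trials
    excluded), mirroring the per-block feedback shown during training."""
    ok = scored[~scored["degenerate"]]
    return (
        ok.groupby(["subject", "group", "day", "condition", "block"], sort=False)[
            ["syn_ms", "rmse"]
        ]
        .mean()
        .reset_index()
    )


def day_means(scored: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition x day means (degenerate trials excluded)."""
    ok = scored[~scored["degenerate"]]
    return (
        ok.groupby(["subject", "group", "day", "condition"], sort=False)[
            ["syn_ms", "rmse"]
        ]
        .mean()
        .reset_index()
    )


def exclude_outliers(
    scored: pd.DataFrame,
    k_sd: float = 2.0,
    min_days: int = 2,
    metrics: tuple[str, ...] = ("syn_ms", "rmse"),
) -> tuple[pd.DataFrame, list[str]]:
    """Flag subjects whose day-mean performance deviates from their group's
    day mean by more than ``k_sd`` group standard deviations on at least
    ``min_days`` days, on either metric.

    Returns the scored table with an ``excluded`` column (rows retained)
    and the list of excluded subjects.
    """
    dm = day_means(scored)
    excluded: set[str] = set()
    for group, gtab in dm.groupby("group"):
        if gtab["subject"].nunique() < 3:
            raise DesignError(
                f"group {group!r} has fewer than 3 subjects; SD-based exclusion unstable"
            )
        for metric in metrics:
            piv = gtab.pivot_table(index="subject", columns=["day", "condition"], values=metric)
            mu = piv.mean(axis=0)
            sd = piv.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z = (piv - mu).abs() / sd
            # a day counts once even if several conditions deviate
            day_hits = (z > k_sd).T.groupby(level="day").any().T
            n_days = day_hits.sum(axis=1)
            excluded |= set(n_days.index[n_days >= min_days])
    out = scored.copy()
    out["excluded"] = out["subject"].isin(excluded)
    return out, sorted(excluded)
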