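"""Reference and response force-trace generators for the sequential pinch
force task (SPFT).

The task displays a reference bar (REF) whose height follows a pre-set
sequence; the participant pinches a force transducer (sampled at 80 Hz) to
make their force bar (FOR) track it. Two reference sequences exist: a
complex, hard-to-predict learning sequence (LRN) and a simple sinusoidal
control (SMP) matched to LRN for dominant frequency, duration, range and
total force. Trials last 18 s and the display spans 5-30 % of each
participant's maximum voluntary force.

The published LRN sequence heights are not public; :func:`gen_ref_lrn`
reproduces the sequence's *properties* (smooth, pseudo-random heights that
span the display range), which is all the downstream scoring and statistics
depend on.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from ..datatypes import ForceTrace, SequencePair
from ..errors import InvalidArgumentError, MatchingError

__all__ = ["gen_ref_lrn", "gen_ref_smp", "gen_for_response", "dominant_frequency"]


def gen_ref_lrn(
    duration_s: float = 18.0,
    fs: float = 80.0,
    force_range: tuple[float, float] = (5.0, 30.0),
    n_segments: int = 12,
    seed: int | np.random.Generator = 0,
) -> ForceTrace:
    """Generate a complex learning (LRN) reference sequence.

    A smooth, shape-preserving (PCHIP) curve is drawn through
    ``n_segments + 1`` pseudo-random target heights. The extreme display
    levels are always among the targets so the trace spans the full range;
    PCHIP interpolation guarantees no overshoot outside it.

    Deterministic for a fixed ``seed``.
    """
    if not duration_s > 0:
        raise InvalidArgumentError(f"duration must be positive, got {duration_s}")
    if not fs > 0:
        raise InvalidArgumentError(f"sampling rate must be positive, got {fs}")
    lo, hi = force_range
    if not lo < hi:
        raise InvalidArgumentError("force_range must satisfy lo < hi")
    if n_segments < 4:
        raise InvalidArgumentError("need at least 4 segments for a non-trivial sequence")

    rng = np.random.default_rng(seed)
    n_knots = n_segments + 1
    heights = rng.uniform(lo, hi, size=n_knots)
    # plant the extremes at interior knots so the sequence spans the range
    interior = rng.choice(np.arange(1, n_knots - 1), size=2, replace=False)
    heights[interior[0]] = lo
    heights[interior[1]] = hi
    # jitter knot spacing so segment durations vary (harder to predict)
    gaps = rng.uniform(0.6, 1.4, size=n_segments)
    knots = np.concatenate([[0.0], np.cumsum(gaps)])
    knots *= duration_s / knots[-1]

    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    # nudge the free knots so the curve mean sits near mid-range; the
    # sinusoidal control can then match the total force by phase alone
    free = np.ones(n_knots, dtype=bool)
    free[interior] = False
    mid = (lo + hi) / 2.0
    samples = PchipInterpolator(knots, heights)(t)
    for _ in range(60):
        err = samples.mean() - mid
        if abs(err) < 0.05:
            break
        heights[free] = np.clip(heights[free] - err, lo, hi)
        samples = PchipInterpolator(knots, heights)(t)
    samples = np.clip(samples, lo, hi)  # guards rounding at the boundary knots
    return ForceTrace(samples=samples, fs=fs, force_range=(lo, hi))


def dominant_frequency(trace: ForceTrace) -> float:
    """Frequency (Hz) of maximum spectral power, excluding the DC bin."""
    x = trace.samples - trace.samples.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(trace.n_samples, d=1.0 / trace.fs)
    k = 1 + int(np.argmax(spec[1:]))
    return float(freqs[k])


def gen_ref_smp(
    matched_to: ForceTrace,
    tolerance: float = 0.02,
) -> SequencePair:
    """Construct the simple sinusoidal control (SMP) sequence matched to a
    learning sequence.

    The sinusoid ``a*sin(2*pi*f*t + phi) + c`` uses the LRN sequence's
    frequency of maximum spectral power (DC excluded), the same duration and
    sampling rate, amplitude/offset matching the LRN min/max, and the phase
    that minimizes the difference in total force (sum over samples).

    Raises
    ------
    MatchingError
        If any of the four matched properties (dominant frequency, duration,
        range, total magnitude) deviates relatively by more than
        ``tolerance``; the error lists all deviations.
    """
    f = dominant_frequency(matched_to)
    lrn = matched_to.samples
    lo, hi = float(lrn.min()), float(lrn.max())
    a = (hi - lo) / 2.0
    c = (hi + lo) / 2.0
    t = matched_to.times
    target_sum = float(lrn.sum())

    def total_force_gap(phi: float) -> float:
        return abs(a * np.sin(2 * np.pi * f * t + phi).sum() + c * t.size - target_sum)

    # coarse grid then local refinement of the phase
    grid = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    gaps = [total_force_gap(p) for p in grid]
    p0 = grid[int(np.argmin(gaps))]
    step = float(grid[1] - grid[0])
    res = minimize_scalar(
        total_force_gap, bounds=(p0 - step, p0 + step), method="bounded",
        options={"xatol": 1e-12},
    )
    phi = float(res.x) if res.fun <= min(gaps) else float(p0)

    smp_samples = a * np.sin(2 * np.pi * f * t + phi) + c
    smp = ForceTrace(samples=smp_samples, fs=matched_to.fs, force_range=matched_to.force_range)

    rng_lrn = hi - lo
    rng_smp = float(smp_samples.max() - smp_samples.min())
    report = {
        "dominant_frequency": abs(dominant_frequency(smp) - f) / f,
        "duration": abs(smp.duration - matched_to.duration) / matched_to.duration,
        "range": abs(rng_smp - rng_lrn) / rng_lrn,
        "total_magnitude": abs(float(smp_samples.sum()) - target_sum) / abs(target_sum),
    }
    bad = {k: v for k, v in report.items() if v > tolerance}
    if bad:
        raise MatchingError(
            f"SMP sequence violates matching tolerance {tolerance}: {bad}", deviations=report
        )
    return SequencePair(lrn_ref=matched_to, smp_ref=smp, match_report=report)


def gen_for_response(
    ref: ForceTrace,
    lag_ms: float,
    noise_sd: float,
    gain: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> ForceTrace:
    """Simulate a participant's force response as a lagged, scaled, noisy
    copy of the reference: ``FOR(t) = gain * REF(t - lag) + noise``.

    The shift is applied at integer-sample resolution with hold-first /
    hold-last edge padding; the result is clipped to the display range when
    the reference declares one.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be nonnegative")
    if not gain > 0:
        raise InvalidArgumentError("gain must be positive")
    half_ms = ref.duration * 1000.0 / 2.0
    if abs(lag_ms) >= half_ms:
        raise InvalidArgumentError(
            f"|lag| must be below half the trial ({half_ms:.0f} ms), got {lag_ms}"
        )
    rng = np.random.default_rng(seed)
    k = int(round(lag_ms / 1000.0 * ref.fs))
    x = ref.samples
    if k > 0:  # response lags behind: shift right, hold first value
        shifted = np.concatenate([np.full(k, x[0]), x[:-k]])
    elif k < 0:  # response anticipates: shift left, hold last value
        shifted = np.concatenate([x[-k:], np.full(-k, x[-1])])
    else:
        shifted = x.copy()
    out = gain * shifted
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.size)
    if ref.force_range is not None:
        out = np.clip(out, *ref.force_range)
    return ForceTrace(samples=out, fs=ref.fs, force_range=ref.force_range)
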