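"""Longitudinal behavioural cohort generator.

Emulates the two-group training design: a learning group (LRN) that trains
on the complex sequence and a control group (SMP) matched for motor
execution. Each training day has 3 blocks; within a block the learning group
performs 3 SMP, 3 rest (RST) and 3 LRN trials while the control group
replaces the LRN trials with SMP, so both groups produce 18 scored trials
per day (LRN group: 9 LRN + 9 SMP; SMP group: 18 SMP). Training days are
d1-d5 with a retention probe at d17.

Each scored trial's response is a lagged noisy copy of its reference; the
per-trial lag is drawn around a group/condition/day schedule mean, which is
how learning curves are planted. The schedule is the single source of truth
for the study conditions the generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datatypes import BehaviourGroundTruth, DAYS_BEHAVIOUR, ForceTrace, SequencePair
from ..errors import ConfigurationError
from .forces import gen_for_response, gen_ref_lrn, gen_ref_smp

__all__ = ["ScheduleCell", "default_schedule", "gen_behaviour_cohort"]


@dataclass(frozen=True)
class ScheduleCell:
    """Planted trial parameters for one (group, condition, day) cell."""

    mean_lag_ms: float
    lag_sd_ms: float
    noise_sd: float


# Default learning curves. The learning group's lag on the complex sequence
# shrinks quickly from d1 to d2, more slowly to d3, then plateaus (the
# fast/slow/retention pattern); lags on the simple sinusoid are flat for
# both groups because the sinusoid requires essentially no learning.
_LRN_LAG_BY_DAY = {"d1": 250.0, "d2": 140.0, "d3": 90.0, "d4": 90.0, "d5": 90.0, "d17": 100.0}
_LRN_SMP_LAG = 80.0
_SMP_SMP_LAG = 70.0
_DEFAULT_LAG_SD = 25.0
_DEFAULT_NOISE_SD = 1.0


def default_schedule(
    days: tuple[str, ...] = DAYS_BEHAVIOUR,
    lag_sd_ms: float = _DEFAULT_LAG_SD,
    noise_sd: float = _DEFAULT_NOISE_SD,
) -> dict[tuple[str, str, str], ScheduleCell]:
    """Schedule mapping (group, condition, day) -> planted parameters."""
    schedule: dict[tuple[str, str, str], ScheduleCell] = {}
    for day in days:
        schedule[("LRN", "LRN", day)] = ScheduleCell(_LRN_LAG_BY_DAY[day], lag_sd_ms, noise_sd)
        schedule[("LRN", "SMP", day)] = ScheduleCell(_LRN_SMP_LAG, lag_sd_ms, noise_sd)
        schedule[("SMP", "SMP", day)] = ScheduleCell(_SMP_SMP_LAG, lag_sd_ms, noise_sd)
    return schedule


# per-block condition order within a day (the scored conditions; rest trials
# carry no traces). The learning group runs SMP, rest, LRN in each block.
_BLOCK_PLAN = {
    "LRN": [("SMP", 3), ("RST", 3), ("LRN", 3)],
    "SMP": [("SMP", 3), ("RST", 3), ("SMP", 3)],
}


def gen_behaviour_cohort(
    n_per_group: int,
    schedule: dict[tuple[str, str, str], ScheduleCell] | None = None,
    days: tuple[str, ...] = DAYS_BEHAVIOUR,
    duration_s: float = 18.0,
    fs: float = 80.0,
    force_range: tuple[float, float] = (5.0, 30.0),
    n_segments: int = 12,
    seed: int = 0,
) -> tuple[dict[str, tuple[ForceTrace, ForceTrace]], pd.DataFrame, BehaviourGroundTruth]:
    """Simulate a full behavioural cohort.

    Returns
    -------
    traces : dict mapping trial key -> (REF, FOR) ForceTrace pair.
    table : long-format cohort metadata (subject, group, day, block, trial,
        condition, trace_key), one row per *scored* trial.
    truth : the planted lags, noise level and group assignment.
    """
    if schedule is None:
        schedule = default_schedule(days=days)
    required = {
        (g, c, d)
        for d in days
        for g, plan in _BLOCK_PLAN.items()
        for c, _ in plan
        if c != "RST"
    }
    missing = sorted(required - set(schedule))
    if missing:
        raise ConfigurationError(f"schedule is missing cells: {missing}")

    root = np.random.default_rng(seed)
    # the reference sequences are shared by every participant and day
    pair: SequencePair = gen_ref_smp(
        gen_ref_lrn(duration_s, fs, force_range, n_segments, seed=root.integers(2**31))
    )
    refs = {"LRN": pair.lrn_ref, "SMP": pair.smp_ref}

    subjects = [(f"lrn{i + 1:02d}", "LRN") for i in range(n_per_group)] + [
        (f"smp{i + 1:02d}", "SMP") for i in range(n_per_group)
    ]

    traces: dict[str, tuple[ForceTrace, ForceTrace]] = {}
    rows, truth_rows = [], []
    noise_sds = set()
    for subject, group in subjects:
        sub_rng = np.random.default_rng(root.integers(2**31))
        for day in days:
            for block in (1, 2, 3):
                trial_no = 0
                for condition, n_trials in _BLOCK_PLAN[group]:
                    for _ in range(n_trials):
                        trial_no += 1
                        if condition == "RST":
                            continue
                        cell = schedule[(group, condition, day)]
                        lag = float(sub_rng.normal(cell.mean_lag_ms, cell.lag_sd_ms))
                        ref = refs[condition]
                        force = gen_for_response(
                            ref, lag, cell.noise_sd, seed=sub_rng.integers(2**31)
                        )
                        key = f"{subject}_{day}_{block}_{trial_no}_{condition}"
                        traces[key] = (ref, force)
                        noise_sds.add(cell.noise_sd)
                        rows.append(
                            dict(
                                subject=subject,
                                group=group,
                                day=day,
                                block=block,
                                trial=trial_no,
                                condition=condition,
                                trace_key=key,
                            )
                        )
                        truth_rows.append(
                            dict(
                                subject=subject,
                                group=group,
                                day=day,
                                block=block,
                                trial=trial_no,
                                condition=condition,
                                lag_ms=lag,
                            )
                        )

    table = pd.DataFrame(rows)
    truth = BehaviourGroundTruth(
        planted_lag_ms=pd.DataFrame(truth_rows),
        planted_noise_sd=max(noise_sds) if len(noise_sds) == 1 else float("nan"),
        group_assignment={s: g for s, g in subjects},
    )
    return traces, table, truth
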