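"""Worked-example regional centrality-change summaries.

A published longitudinal motor-learning study of this design reported, for
each region with a significant group-by-time interaction, the per-group
mean EC change with SEM and 95% CI across the relevant learning stage.
Those printed summary statistics are reproduced here as the canonical
worked example for :func:`seqmotor.inference.classify_specificity`: feeding
them to the classifier must reproduce the study's sequence-specificity
assignments (only the right SMA, overall learning, is driven by the
learning group and hence sequence-specific).

Values are unitless EC changes as printed (two decimals).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["regional_change_examples", "EXPECTED_DRIVING", "EXPECTED_SPECIFIC"]

_ROWS = [
    # stage, region, LRN mean, LRN sem, LRN ci, SMP mean, SMP sem, SMP ci
    ("fast", "R AIC", -0.05, 0.03, (-0.10, 0.01), 0.10, 0.03, (0.04, 0.16)),
    ("fast", "R SPC", 0.06, 0.03, (-0.01, 0.12), -0.12, 0.03, (-0.19, -0.04)),
    ("slow", "R AIC", 0.02, 0.03, (-0.04, 0.08), -0.13, 0.02, (-0.17, -0.10)),
    ("retention", "R Putamen", -0.02, 0.02, (-0.06, 0.03), 0.12, 0.03, (0.06, 0.19)),
    ("overall", "R SMA", -0.10, 0.02, (-0.14, -0.06), 0.03, 0.02, (-0.02, 0.08)),
    ("overall", "R PO", -0.05, 0.02, (-0.10, -0.00), 0.09, 0.03, (0.03, 0.16)),
    ("overall", "L SPC", 0.06, 0.02, (0.02, 0.11), -0.12, 0.03, (-0.19, -0.06)),
    ("overall", "R SPC", 0.05, 0.03, (-0.01, 0.12), -0.13, 0.04, (-0.21, -0.04)),
]

#: The study's assignments: which group drove each regional change, and
#: which effects were called sequence-specific.
EXPECTED_DRIVING = {
    ("fast", "R AIC"): "SMP",
    ("fast", "R SPC"): "SMP",
    ("slow", "R AIC"): "SMP",
    ("retention", "R Putamen"): "SMP",
    ("overall", "R SMA"): "LRN",
    ("overall", "R PO"): "SMP",
    ("overall", "L SPC"): "SMP",
    ("overall", "R SPC"): "SMP",
}
EXPECTED_SPECIFIC = {key: key == ("overall", "R SMA") for key in EXPECTED_DRIVING}


def regional_change_examples() -> pd.DataFrame:
    """The worked-example table, one row per (stage, region)."""
    records = []
    for stage, region, lm, ls, lci, sm, ss, sci in _ROWS:
        records.append(
            dict(
                stage=stage,
                region=region,
                lrn_mean=lm,
                lrn_sem=ls,
                lrn_ci_lo=lci[0],
                lrn_ci_hi=lci[1],
                smp_mean=sm,
                smp_sem=ss,
                smp_ci_lo=sci[0],
                smp_ci_hi=sci[1],
            )
        )
    return pd.DataFrame(records)


def change_dict(row) -> dict:
    """Convert one example row into the change mapping that
    classify_specificity consumes."""
    return {
        "LRN": dict(
            mean=row["lrn_mean"],
            sem=row["lrn_sem"],
            ci95=(row["lrn_ci_lo"], row["lrn_ci_hi"]),
            n=None,
        ),
        "SMP": dict(
            mean=row["smp_mean"],
            sem=row["smp_sem"],
            ci95=(row["smp_ci_lo"], row["smp_ci_hi"]),
            n=None,
        ),
    }
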