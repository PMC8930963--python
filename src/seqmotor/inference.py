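"""Group-by-time interaction inference on eigenvector centrality maps.

For a balanced two-group, two-occasion design the interaction contrast of
the full longitudinal factorial model reduces to a two-sample t test on the
per-subject change maps (EC at the later day minus EC at the earlier day),
which also permits exact group-label permutation inference. Four learning
stages are tested, each in both directions (8 directional contrasts):
fast (d1,d2), slow (d2,d5), overall (d1,d5) and retention (d5,d17).

Cluster-level inference: the t map is thresholded at the one-sided t
quantile for the primary p (default 0.001), suprathreshold voxels are
grouped into connected components (18-connectivity by default), and the
null distribution of cluster sizes is built by re-computing the t map under
group-label permutations and pooling all suprathreshold cluster sizes.
Per-cluster permutation p values are Benjamini-Hochberg corrected across
the observed clusters (cluster-level FDR, default 0.05).

A significant cluster is *sequence-specific* when the learning (LRN) group
drives the change — its mean ROI change excludes zero while the control
(SMP) group's does not.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ClusterResult,
    ECMap,
    GroupTrajectory,
    SpecificityVerdict,
    StageContrast,
    TMap,
    stage_contrasts,
)
from .errors import DesignError, InvalidArgumentError

__all__ = [
    "delta_matrix",
    "interaction_tmap",
    "find_clusters",
    "cluster_inference",
    "baseline_ec_test",
    "roi_trajectory",
    "classify_specificity",
    "interaction_analysis",
    "stage_report",
    "stage_contrasts",
]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}
_EXACT_ENUMERATION_LIMIT = 10_000


def _common_mask(maps: list[ECMap]) -> np.ndarray:
    mask = maps[0].mask.copy()
    for m in maps[1:]:
        if m.mask.shape != mask.shape:
            raise InvalidArgumentError("EC maps live on different grids")
        mask &= m.mask
    return mask


def delta_matrix(
    ec_maps: dict[tuple[str, str], ECMap],
    groups: dict[str, str],
    day_pair: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Per-subject EC change vectors for a day pair.

    Returns (deltas [subjects x voxels], labels [bool, True = LRN],
    mask, subjects).
    """
    d_from, d_to = day_pair
    subjects = sorted({s for (s, _d) in ec_maps})
    missing = [
        s for s in subjects if (s, d_from) not in ec_maps or (s, d_to) not in ec_maps
    ]
    if missing:
        raise InvalidArgumentError(f"subjects missing a session for {day_pair}: {missing}")
    all_maps = [ec_maps[(s, d)] for s in subjects for d in day_pair]
    mask = _common_mask(all_maps)
    deltas = np.stack(
        [ec_maps[(s, d_to)].values[mask] - ec_maps[(s, d_from)].values[mask] for s in subjects]
    )
    labels = np.array([groups[s] == "LRN" for s in subjects])
    if labels.all() or not labels.any():
        raise DesignError("both groups must be present")
    return deltas, labels, mask, subjects


def _two_sample_t(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t (LRN minus SMP) per column."""
    a, b = values[labels], values[~labels]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (ma - mb) / np.where(se > 0, se, 1.0), 0.0)
    return t


def interaction_tmap(
    ec_maps: dict[tuple[str, str], ECMap],
    groups: dict[str, str],
    stage: StageContrast,
) -> TMap:
    """Voxelwise interaction t map for a directional stage contrast.

    Positive t means the data favour the contrast: for ``decrease``, the
    LRN group's EC drops more than the SMP group's over the day pair.
    """
    deltas, labels, mask, _ = delta_matrix(ec_maps, groups, stage.day_pair)
    t_flat = _two_sample_t(deltas, labels)
    if stage.direction == "decrease":
        t_flat = -t_flat
    t3d = np.zeros(mask.shape)
    t3d[mask] = t_flat
    return TMap(t=t3d, df=deltas.shape[0] - 2, mask=mask, contrast=stage)


def find_clusters(
    t3d: np.ndarray, threshold: float, connectivity: int = 18
) -> tuple[np.ndarray, list[dict]]:
    """Connected suprathreshold components of a t map.

    Returns the labelled volume and a list of cluster records (label, size,
    peak t, peak voxel coordinate), sorted by decreasing size.
    """
    if connectivity not in _CONNECTIVITY:
        raise InvalidArgumentError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    supra = t3d > threshold
    labelled, n = ndimage.label(supra, structure=structure)
    records = []
    for lab in range(1, n + 1):
        m = labelled == lab
        size = int(m.sum())
        idx = np.argwhere(m)
        peak_local = np.argmax(t3d[m])
        peak = tuple(int(v) for v in idx[peak_local])
        records.append(
            dict(label=lab, size=size, peak_t=float(t3d[m].max()), peak_coordinate=peak)
        )
    records.sort(key=lambda r: -r["size"])
    return labelled, records


def _null_cluster_sizes(
    deltas: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    sign: float,
    threshold: float,
    connectivity: int,
    n_perm: int,
    seed,
) -> np.ndarray:
    """Pooled suprathreshold cluster sizes under group-label permutation.

    Enumerates all distinct labelings when there are at most 10,000 of
    them; otherwise samples ``n_perm`` random permutations.
    """
    n = labels.size
    n_lrn = int(labels.sum())
    sizes: list[int] = []
    t3d = np.zeros(mask.shape)

    def collect(lab_vec):
        t_flat = sign * _two_sample_t(deltas, lab_vec)
        t3d[mask] = t_flat
        _, recs = find_clusters(t3d, threshold, connectivity)
        sizes.extend(r["size"] for r in recs)

    if comb(n, n_lrn) <= _EXACT_ENUMERATION_LIMIT:
        for idx in combinations(range(n), n_lrn):
            lab = np.zeros(n, dtype=bool)
            lab[list(idx)] = True
            collect(lab)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            collect(rng.permutation(labels))
    return np.asarray(sizes, dtype=int)


def cluster_inference(
    deltas: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    direction: str = "decrease",
    primary_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 18,
    seed: int | None = 0,
    keep_all: bool = False,
) -> list[ClusterResult]:
    """Permutation cluster-level inference on per-subject change vectors.

    ``deltas`` is subjects x in-mask voxels, ``labels`` marks LRN subjects.
    Returns the clusters surviving cluster-level FDR (all observed clusters
    when ``keep_all``), annotated with permutation p and BH q.
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be at least 100")
    df = deltas.shape[0] - 2
    threshold = float(stats.t.ppf(1 - primary_p, df))
    sign = -1.0 if direction == "decrease" else 1.0

    t3d = np.zeros(mask.shape)
    t3d[mask] = sign * _two_sample_t(deltas, labels)
    labelled, records = find_clusters(t3d, threshold, connectivity)
    if not records:
        return []

    null_sizes = _null_cluster_sizes(
        deltas, labels, mask, sign, threshold, connectivity, n_perm, seed
    )
    n_null = null_sizes.size
    p_vals = [
        (1.0 + int((null_sizes >= r["size"]).sum())) / (1.0 + n_null) for r in records
    ]
    _, q_vals, _, _ = multipletests(p_vals, method="fdr_bh")
    results = []
    for r, p, q in zip(records, p_vals, q_vals):
        if keep_all or q < cluster_alpha:
            results.append(
                ClusterResult(
                    label=r["label"],
                    size=r["size"],
                    peak_t=r["peak_t"],
                    peak_coordinate=r["peak_coordinate"],
                    p_uncorrected=float(p),
                    q_fdr=float(q),
                    mask=labelled == r["label"],
                )
            )
    return results


def baseline_ec_test(
    ec_maps: dict[tuple[str, str], ECMap],
    groups: dict[str, str],
    day: str,
    primary_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 18,
    seed: int | None = 0,
) -> tuple[TMap, list[ClusterResult]]:
    """Two-sided voxelwise two-sample t test of the groups' EC maps at a
    single (pre-training) day, with cluster inference on |t|."""
    subjects = sorted({s for (s, d) in ec_maps if d == day})
    if not subjects:
        raise InvalidArgumentError(f"no EC maps at day {day!r}")
    maps = [ec_maps[(s, day)] for s in subjects]
    mask = _common_mask(maps)
    values = np.stack([m.values[mask] for m in maps])
    labels = np.array([groups[s] == "LRN" for s in subjects])
    if labels.all() or not labels.any():
        raise DesignError("both groups must be present at the baseline day")

    df = values.shape[0] - 2
    t_flat = _two_sample_t(values, labels)
    t3d = np.zeros(mask.shape)
    t3d[mask] = t_flat
    tmap = TMap(t=t3d, df=df, mask=mask, contrast=None)

    threshold = float(stats.t.ppf(1 - primary_p / 2.0, df))  # two-sided primary
    abs3d = np.abs(t3d)
    labelled, records = find_clusters(abs3d, threshold, connectivity)
    if not records:
        return tmap, []
    # permutation null on |t|
    sizes: list[int] = []
    n = labels.size
    n_lrn = int(labels.sum())
    tmp = np.zeros(mask.shape)
    if comb(n, n_lrn) <= _EXACT_ENUMERATION_LIMIT:
        labelings = (
            np.isin(np.arange(n), idx) for idx in combinations(range(n), n_lrn)
        )
    else:
        rng = np.random.default_rng(seed)
        labelings = (rng.permutation(labels) for _ in range(n_perm))
    for lab in labelings:
        tmp[mask] = np.abs(_two_sample_t(values, np.asarray(lab)))
        _, recs = find_clusters(tmp, threshold, connectivity)
        sizes.extend(r["size"] for r in recs)
    null_sizes = np.asarray(sizes)
    p_vals = [
        (1.0 + int((null_sizes >= r["size"]).sum())) / (1.0 + null_sizes.size)
        for r in records
    ]
    _, q_vals, _, _ = multipletests(p_vals, method="fdr_bh")
    clusters = [
        ClusterResult(
            label=r["label"],
            size=r["size"],
            peak_t=r["peak_t"],
            peak_coordinate=r["peak_coordinate"],
            p_uncorrected=float(p),
            q_fdr=float(q),
            mask=labelled == r["label"],
        )
        for r, p, q in zip(records, p_vals, q_vals)
        if q < cluster_alpha
    ]
    return tmap, clusters


def _summary(x: np.ndarray) -> dict:
    n = x.size
    mean = float(x.mean()) if n else float("nan")
    if n < 2:
        return dict(mean=mean, sem=float("nan"), ci95=(float("nan"), float("nan")), n=n)
    sem = float(x.std(ddof=1) / np.sqrt(n))
    tq = float(stats.t.ppf(0.975, n - 1))
    return dict(mean=mean, sem=sem, ci95=(mean - tq * sem, mean + tq * sem), n=n)


def roi_trajectory(
    ec_maps: dict[tuple[str, str], ECMap],
    cluster_mask: np.ndarray,
    groups: dict[str, str],
    days: list[str],
    day_pair: tuple[str, str],
) -> GroupTrajectory:
    """Mean EC within an ROI, per group and day, plus the stage-change
    summary (mean, SEM, t-based 95% CI per group)."""
    cluster_mask = np.asarray(cluster_mask).astype(bool)
    if not cluster_mask.any():
        raise InvalidArgumentError("cluster mask is empty")
    subjects = sorted({s for (s, _d) in ec_maps})
    roi_means: dict[tuple[str, str], float] = {}
    for s in subjects:
        for d in days:
            if (s, d) not in ec_maps:
                raise InvalidArgumentError(f"missing EC map for ({s}, {d})")
            m = ec_maps[(s, d)]
            inter = cluster_mask & m.mask
            if not inter.any():
                raise InvalidArgumentError("cluster lies outside the analysis mask")
            roi_means[(s, d)] = float(m.values[inter].mean())

    per_day: dict[str, pd.DataFrame] = {}
    change: dict[str, dict] = {}
    for group in ("LRN", "SMP"):
        subs = [s for s in subjects if groups[s] == group]
        rows = []
        for d in days:
            rows.append(dict(day=d, **_summary(np.array([roi_means[(s, d)] for s in subs]))))
        per_day[group] = pd.DataFrame(rows)
        d_from, d_to = day_pair
        deltas = np.array([roi_means[(s, d_to)] - roi_means[(s, d_from)] for s in subs])
        change[group] = _summary(deltas)
    return GroupTrajectory(
        roi=cluster_mask, days=list(days), per_day=per_day, change=change, day_pair=day_pair
    )


def classify_specificity(
    trajectory: GroupTrajectory | dict, stage: StageContrast | None = None
) -> SpecificityVerdict:
    """Decide which group drives an ROI's centrality change and whether the
    effect is sequence-specific.

    The driving group is the one with the larger absolute mean change among
    groups whose 95% CI excludes zero (``none`` when neither does; when
    both do, the larger magnitude wins and the tie is recorded). The effect
    is sequence-specific iff the LRN group drives it and the SMP group's CI
    contains zero.
    """
    change = trajectory.change if isinstance(trajectory, GroupTrajectory) else trajectory
    for g in ("LRN", "SMP"):
        if g not in change:
            raise DesignError(f"trajectory missing group {g!r}")

    def excludes_zero(g):
        lo, hi = change[g]["ci95"]
        return (lo > 0) or (hi < 0)

    candidates = [g for g in ("LRN", "SMP") if excludes_zero(g)]
    rationale = {
        g: dict(
            mean=change[g]["mean"], ci95=tuple(change[g]["ci95"]), excludes_zero=excludes_zero(g)
        )
        for g in ("LRN", "SMP")
    }
    if not candidates:
        driving = "none"
    elif len(candidates) == 1:
        driving = candidates[0]
    else:
        driving = max(candidates, key=lambda g: abs(change[g]["mean"]))
        rationale["tie_break"] = "both CIs exclude zero; larger |mean| wins"
    specific = driving == "LRN" and not excludes_zero("SMP")
    return SpecificityVerdict(
        driving_group=driving, sequence_specific=specific, rationale=rationale
    )


def interaction_analysis(
    ec_maps: dict[tuple[str, str], ECMap],
    groups: dict[str, str],
    stage: StageContrast,
    days: list[str] | None = None,
    primary_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 18,
    seed: int | None = 0,
) -> dict:
    """One directional stage contrast end to end: t map, significant
    clusters, per-cluster trajectories and specificity verdicts."""
    deltas, labels, mask, _subjects = delta_matrix(ec_maps, groups, stage.day_pair)
    tmap = interaction_tmap(ec_maps, groups, stage)
    clusters = cluster_inference(
        deltas,
        labels,
        mask,
        direction=stage.direction,
        primary_p=primary_p,
        cluster_alpha=cluster_alpha,
        n_perm=n_perm,
        connectivity=connectivity,
        seed=seed,
    )
    if days is None:
        days = sorted({d for (_s, d) in ec_maps})
    out = {"stage": stage, "tmap": tmap, "clusters": []}
    for cl in clusters:
        traj = roi_trajectory(ec_maps, cl.mask, groups, days, stage.day_pair)
        verdict = classify_specificity(traj, stage)
        out["clusters"].append({"cluster": cl, "trajectory": traj, "verdict": verdict})
    return out


def stage_report(analyses: list[dict]) -> dict:
    """Consolidate stage analyses into two tables: per-cluster statistics
    (contrast, q, size, peak) and per-cluster per-group change summaries
    with the specificity flag. Returns dict with 'clusters' and 'summary'
    DataFrames plus a JSON-ready 'json' payload."""
    cluster_rows, summary_rows = [], []
    for res in analyses:
        stage: StageContrast = res["stage"]
        for entry in res["clusters"]:
            cl: ClusterResult = entry["cluster"]
            verdict: SpecificityVerdict = entry["verdict"]
            traj: GroupTrajectory = entry["trajectory"]
            cluster_rows.append(
                dict(
                    stage=stage.name,
                    day_pair=f"{stage.day_pair[0]}-{stage.day_pair[1]}",
                    direction=stage.direction,
                    q_fdr=cl.q_fdr,
                    K=cl.size,
                    peak_t=cl.peak_t,
                    peak_x=cl.peak_coordinate[0],
                    peak_y=cl.peak_coordinate[1],
                    peak_z=cl.peak_coordinate[2],
                )
            )
            for group in ("LRN", "SMP"):
                ch = traj.change[group]
                summary_rows.append(
                    dict(
                        stage=stage.name,
                        direction=stage.direction,
                        cluster=cl.label,
                        group=group,
                        mean=ch["mean"],
                        sem=ch["sem"],
                        ci95_lo=ch["ci95"][0],
                        ci95_hi=ch["ci95"][1],
                        driving_group=verdict.driving_group,
                        sequence_specific=verdict.sequence_specific,
                    )
                )
    clusters_df = pd.DataFrame(
        cluster_rows,
        columns=[
            "stage", "day_pair", "direction", "q_fdr", "K",
            "peak_t", "peak_x", "peak_y", "peak_z",
        ],
    )
    summary_df = pd.DataFrame(
        summary_rows,
        columns=[
            "stage", "direction", "cluster", "group", "mean", "sem",
            "ci95_lo", "ci95_hi", "driving_group", "sequence_specific",
        ],
    )
    payload = {
        "clusters": clusters_df.to_dict(orient="records"),
        "summary": summary_df.to_dict(orient="records"),
        "peak_coordinate_convention": "0-based voxel indices",
    }
    return {"clusters": clusters_df, "summary": summary_df, "json": payload}
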