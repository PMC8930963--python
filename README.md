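# seqmotor

Analysis pipeline for **sequence-specific motor learning** experiments that
pair a continuous pinch-force tracking task with longitudinal resting-state
fMRI. It is written for researchers who want to separate *learning a
specific motor sequence* from *mere motor execution*: a learning group
trains on a complex force sequence (LRN) while a control group performs a
matched simple sinusoid (SMP), both over five training days (d1–d5) plus a
retention probe (d17), with resting-state scans on d0, d1, d2, d5 and d17.

The package covers the whole chain, end to end, on synthetic data (raw
data of such studies typically cannot be shared):

1. **Task simulation** (`seqmotor.synthetic`) — reference force sequences
   sampled at 80 Hz over 18 s trials spanning 5–30 % of maximum voluntary
   force; the sinusoidal control is matched to the complex sequence for
   dominant frequency, duration, range and total force. Behavioural
   cohorts follow the 3-blocks-of-9-trials daily structure; BOLD phantoms
   plant region-structured connectivity whose hub coupling ramps down
   across sessions in one group only.
2. **Behavioural scoring** (`seqmotor.scoring`) — per-trial temporal
   synchronization **SYN** (the cross-correlation lag, in ms, at which the
   participant's force curve best matches the reference; 0 = perfect
   timing) and **lag-aligned RMSE** (spatial tracking error after removing
   the lag), plus block/day aggregation and the ±2 SD / ≥2 days outlier
   rule.
3. **Behavioural statistics** (`seqmotor.behaviour_stats`) — Welch t test
   on day-1 first-block control trials, mixed-design ANOVA (within factor
   *day*, between factor over the three performance traces) with Mauchly's
   sphericity test and Greenhouse–Geisser / Huynh–Feldt correction, and
   Tukey HSD post hocs between consecutive days.
4. **BOLD cleaning** (`seqmotor.preprocess`) — drop 5 initial volumes,
   12 motion regressors + spike indicators + aCompCor components from
   WM/CSF, nuisance regression, detrend, variance-normalize, zero-phase
   0.01–0.1 Hz bandpass, mask-aware 2.4 mm FWHM Gaussian smoothing.
5. **Eigenvector centrality mapping** (`seqmotor.centrality`) — every
   voxel is a node; the similarity matrix is `M = (C + 1)/2` with `C` the
   voxelwise Pearson correlation matrix, so `M` is positive and the
   dominant eigenvector is unique and nonnegative (Perron–Frobenius).
   `fast_ecm` computes it matrix-free by power iteration,

       M v = ( Z (Zᵀ v) / T + 1·Σv ) / 2,

   with `Z` the voxel × time array of z-scored series, at O(voxels × time)
   per iteration; `dense_ecm` is the explicit-matrix oracle.
6. **Interaction inference** (`seqmotor.inference`) — the group × time
   interaction for the four learning stages (fast d1→d2, slow d2→d5,
   overall d1→d5, retention d5→d17), each in both directions, as
   two-sample t tests on per-subject EC-change maps; cluster formation at
   the one-sided p < 0.001 primary threshold (18-connectivity);
   permutation null over group labelings (exact enumeration when
   feasible); Benjamini–Hochberg FDR over clusters at q < 0.05; ROI
   change trajectories; and the **sequence-specificity rule**: an effect
   is sequence-specific iff the learning group drives it (its 95 % CI of
   mean ΔEC excludes zero) while the control group's CI contains zero.

## Worked example

```python
from seqmotor.config import PipelineConfig
from seqmotor.datatypes import StageContrast
from seqmotor.inference import interaction_analysis
from seqmotor.pipeline import compute_ec_maps
from seqmotor.synthetic import gen_bold_cohort

datasets, truth = gen_bold_cohort(n_per_group=10, days=("d1", "d5"), seed=7)
ec_maps = compute_ec_maps(datasets, PipelineConfig(n_perm=500))
groups = {s: ("LRN" if s.startswith("lrn") else "SMP") for (s, _d) in ec_maps}
res = interaction_analysis(
    ec_maps, groups,
    StageContrast("overall", ("d1", "d5"), "decrease"),
    n_perm=500, seed=7,
)
for entry in res["clusters"]:
    cl, v = entry["cluster"], entry["verdict"]
    print(f"cluster K={cl.size} peak_t={cl.peak_t:.2f} q={cl.q_fdr:.3f} "
          f"driving={v.driving_group} sequence_specific={v.sequence_specific}")
```

prints (seed 7):

```
cluster K=31 peak_t=12.73 q=0.003 driving=LRN sequence_specific=True
```

i.e. the overall-learning decrease contrast recovers one significant
cluster — 31 voxels, peak t = 12.73, cluster-level q = 0.003 — that
coincides with the phantom's planted effect region, and the
centrality decrease is driven by the learning group with a quiet control
group, so the verdict is *sequence-specific*. The classifier applied to
the bundled worked-example table of published regional change summaries
(`seqmotor.reference_tables`) labels exactly one of eight regions
(right SMA, overall learning) sequence-specific.

A command-line interface mirrors the library:

```bash
seqmotor simulate behaviour --n-per-group 6 --seed 1 --out sim/
seqmotor score --cohort sim/cohort.tsv --out scores.tsv
seqmotor stats --scores scores.tsv --dv syn_ms --out stats.json
seqmotor run-all --seed 1 --out run/
```

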