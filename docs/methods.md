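# Methods

This note documents the models, numerical choices and limitations behind
`seqmotor`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model and behavioural scoring

The sequential pinch force task displays a reference bar (REF) whose
height follows a pre-set sequence; the participant's pinch force drives a
second bar (FOR). Trials are 18 s at 80 Hz; the display spans 5–30 % of
each participant's maximum voluntary force. Two sequences exist: a
complex, hard-to-predict learning sequence and a simple sinusoid matched
to it for dominant frequency, duration, range and total force. The true
published sequence heights are not public, so `gen_ref_lrn` reproduces
the *properties* that the downstream analysis depends on: a smooth
shape-preserving (PCHIP) curve through pseudo-random knot heights that
span the display range, with jittered knot spacing. The free knots are
nudged deterministically so the curve mean sits near mid-range — a
precondition for the sinusoidal control to match total force by phase
alone, since a range-matched sinusoid's mean is pinned to mid-range.

`gen_ref_smp` builds the control as `a·sin(2πft+φ)+c` with `f` the
frequency of maximum spectral power of the learning sequence (DC
excluded), `a`/`c` fixed by its min/max, and `φ` minimizing the total
force difference (coarse grid over 256 phases, then bounded scalar
refinement). Matching is verified (four relative deviations, tolerance
2 %) and fails loudly rather than silently.

Simulated responses are `gain·REF(t−lag)+noise`, integer-sample shifts
with hold-first/hold-last edge padding (wrap-around padding would bias
lag recovery), clipped to the display range. Clipping slightly trims
noise variance near the display edges; the tests therefore check the
noise calibration on the interior of the force range.

**SYN** is the signed lag maximizing the Pearson cross-correlation over
integer sample lags within ±3 s (12.5 ms granularity; no sub-sample
interpolation), ties broken toward the smaller |lag| and then the
positive lag. Each candidate lag uses the overlapping support only.
**Lag-aligned RMSE** shifts FOR back by the estimated lag and takes
√mean((REF−FOR)²) over the overlap; trials whose overlap falls below
half the trial are flagged degenerate, as are zero-variance traces.

The outlier rule excludes a subject whose day-mean deviates from the
group's day mean by more than 2 group SDs on at least 2 days, on either
metric, computed within group; groups below 3 subjects are refused
because the SD is unstable.

## Behavioural statistics

The mixed-design ANOVA uses a within factor *day* (d1–d5, d17) and, by
default, a three-level between factor over performance traces — the
learning group's complex-sequence trials, the learning group's control
trials, and the control group's trials — because the learning group
produces two distinct performance traces per day; each (subject, trace)
pair is one observational unit. A two-level group coding is available.
Sums of squares are the textbook balanced-design partition; sphericity is
tested with Mauchly's W (with the second-order Box correction to the χ²
approximation), and when it rejects, degrees of freedom are scaled by the
Greenhouse–Geisser epsilon if ε_GG < 0.75 and Huynh–Feldt otherwise.
Effect size is partial η². The test suite cross-checks F, df, p, ε and
Mauchly's p against pingouin and the Tukey HSD p values against
scipy.stats.tukey_hsd at 1e-8; the baseline comparison is a Welch
(unequal-variance) t test on day-1 first-block control-sequence averages,
the safer default when no variance assumption is stated. Confidence
intervals use the t quantile with n−1 df, not 1.96, given small n.

## BOLD phantom

`gen_bold_cohort` emulates the statistical structure the interaction
analysis assumes, not BOLD physics (no hemodynamic convolution, no
scanner artifacts, no distortion; phantoms are generated already
"aligned"). Geometry: a spherical brain, with white-matter and CSF
compartments as disjoint shells; inside the brain, a central hub sphere,
three satellite spheres, and small cubic (3-voxel) filler parcels tiling
the remaining brain volume. Latent region signals are band-limited to
0.01–0.1 Hz (so cleaning does not destroy planted structure), then mixed
by empirical whitening followed by a symmetric matrix square root, which
makes the realized latent correlation matrix equal the per-(group, day)
target *exactly* for every finite series. Targets follow a single-factor
structure — satellites couple to the hub at 0.6, fillers at 0.3,
satellite–satellite correlations are products of hub couplings — which is
positive semidefinite by construction; arbitrary user-supplied matrices
are validated and rejected per session if not PSD.

Voxels load on their parcel latent with session-stable positive loadings
(mean 1, SD 0.1) shaped by a radial taper (1 at the region center to 0.3
at the boundary, giving graded rather than all-or-nothing connectivity
profiles) plus white noise (SD 0.45). WM/CSF voxels carry shared
sinusoidal "physiological" components plus noise, which is what the
aCompCor step recovers. Motion parameters are small random walks.

The planted group × time effect ramps the effect region's hub coupling
0.6 → 0.2 across d1 → d5 in the learning group only (d2 at 0.45; d17
stays at 0.2), so baseline days show no group difference.

Default phantom scale: 20³ grid, 2.4 mm voxels, 300 volumes, TR 1.13 s.
These are deliberate desk-scale choices: at 2.4 mm the study's 2.4 mm
FWHM smoothing kernel is sub-voxel, as it should be for a grid that
stands in for a whole brain at ~8× coarser resolution; 300 volumes
(scaled down from the 512 a full acquisition provides) keeps enough
effective degrees of freedom in the band-limited series — roughly T/5 —
for within-session correlation estimates to resolve the planted 0.4
coupling change; and tiling the brain with parcels rather than leaving
unstructured-noise voxels mirrors real eigenvector-centrality maps,
whose spatial structure is parcellated, and keeps the dominant
eigenvector stable across sessions.

What passing tests show — and what they do not: the phantom validates
the *inference machinery* (recovery, calibration, specificity logic)
under a known truth with exact latent correlations and stationary noise.
Real data add head motion coupled to the signal, physiological
confounds, registration error and non-stationarity; passing here does
not certify performance under those.

## Cleaning

Order: confound regression (OLS, intercept always included, collinear
columns dropped greedily with a warning) → linear detrend →
variance-normalize → zero-phase order-4 Butterworth bandpass (0.01–0.1 Hz
via forward–backward filtering) → final re-standardization. The final
step exists because filtering necessarily removes variance, so without it
the "unit variance per in-mask voxel" output contract cannot hold; with
it, every in-mask voxel leaves the cleaner with exactly zero mean and
unit variance (pre-smoothing). Exact idempotence is impossible for any
real filter — a second pass re-attenuates band-edge content (~15 %
reshaping in L2 for white-noise input) — so the re-application property
is tested as per-voxel correlation > 0.95 between passes. Voxels whose
residual variance collapses (e.g. a voxel equal to a confound) are
flagged degenerate and removed from the mask.

Composite motion converts rotations to arc length on a 50 mm sphere;
spike volumes are |z| > 3 outliers of composite frame-to-frame motion or
global mean signal, one one-hot regressor each. aCompCor components are
the first 5 left singular vectors of the top-2 %-variance voxels per
tissue (delegated to nilearn's high-variance-confounds routine, the
conventional implementation of this variant). Smoothing is mask-aware
(normalized by the smoothed mask so edges are not dimmed), σ =
FWHM/(2√(2 ln 2))/voxel size.

## Eigenvector centrality

Nodes are in-mask voxels; similarity is `M = (C+1)/2`, mapping Pearson
correlations into [0, 1]. Strict positivity gives a unique positive
dominant eigenvector (Perron–Frobenius), so power iteration from the
uniform positive unit vector — chosen over a random start for determinism
and to start inside the positive cone — converges without deflation. The
matrix-free product uses `C = Z Zᵀ/T` on z-scored rows (population
normalization; any consistent scaling cancels in the eigenvector, which
is asserted by a scale-invariance test). Convergence is declared when the
L2 change of the iterate falls below 1e-9 (default; max 1000 iterations);
non-convergence returns the map flagged `converged=False` with a warning
rather than raising. The Rayleigh quotient of the final iterate estimates
the dominant eigenvalue and is cross-checked against the dense oracle.
`dense_ecm` materializes `M` (guarded at 5000 voxels) and solves the
symmetric eigenproblem. An |C| similarity is exposed as an option but is
not the default: it loses the uniqueness guarantee when the graph
decomposes, and it admits no matrix-free product, so it is guarded like
the dense path. Zero-variance voxels are dropped from the mask with a
warning. Near-degenerate spectra cannot produce ties (M is strictly
positive) but do slow convergence; this surfaces in the iteration count.

Temporal subsampling: halving a session leaves the half-series
correlation estimates only ~20–45 effective dof, so the voxelwise EC map
correlates imperfectly between half and full series (tested > 0.5); the
structural gradient — strongly hub-coupled regions above weakly coupled
fillers — is preserved, which is the property group inference relies on.

## Interaction inference

For a balanced two-group, two-occasion design, the interaction contrast
of a full longitudinal factorial model equals a two-sample t test on
per-subject change maps, and this formulation permits exact group-label
permutation; the package therefore implements the interaction that way.
Four stages × two directions give the 8 one-sided contrasts. Clusters
form at the one-sided t quantile for p < 0.001 with 18-connectivity
(faces + edges; 6 and 26 selectable). The null distribution pools *all*
suprathreshold cluster sizes across permutations — exact enumeration of
group labelings when there are at most 10,000, else sampled permutations
— and each observed cluster gets p = (1 + #null ≥ K)/(1 + N), followed
by Benjamini–Hochberg across observed clusters at q < 0.05. This
permutation route replaces random-field-theory cluster p-values, which
are not reproducible without RFT machinery; it is a deliberate method
substitution and is calibrated by the null-phantom tests.

ROI trajectories average EC within a cluster per subject and day; group
summaries report mean, SEM and t-based 95 % CIs of the per-day values and
of the stage change. The specificity rule: the driving group is the one
with the larger |mean ΔEC| among groups whose CI excludes zero (none if
neither; when both exclude zero the larger magnitude wins and the tie is
recorded — this tie-break is required to reproduce the worked-example
parietal assignments); the effect is sequence-specific iff the learning
group drives it and the control group's CI contains zero. The CI-based
reading formalizes "little to no change" in the control group; it is one
defensible formalization and is validated against the bundled
worked-example table (8/8 label agreement). Peak coordinates are 0-based
voxel indices (phantoms share a grid; no template registration is in
scope).

Baseline group equivalence is checked by two-sided voxelwise t tests on
the EC maps of each pre-training day with the same cluster machinery on
|t|.

## Problem sizes

The test suite and acceptance script choose sizes so a complete run fits
comfortably on one CPU: the centrality oracle battery uses 20 phantoms of
150–500 voxels and 100–300 volumes; lag recovery uses 1000 noisy trials;
the type-I calibrations use 1000 baseline-t replicates and 100 (suite) or
200 (acceptance) null phantom cohorts at 16³ with 6 subjects per group
and 120 volumes; planted-effect recovery runs the default phantom
(n = 10/group) for 6 seeds in the suite and 20 in the acceptance script,
with 500 permutations per contrast.

## Known limitations

- No motion correction, distortion correction, segmentation or template
  registration: those require real scanner data and external toolchains.
- No slice-timing correction (short-TR acquisitions do not need it) and
  no hemodynamic modelling in the phantom.
- The permutation null is contaminated under strong alternatives (label
  permutations partially carry the effect), which makes cluster p-values
  conservative; this is inherent to permutation tests, not specific to
  the pooled-size variant used here.
- The mixed ANOVA assumes balanced day coverage; units missing a day are
  dropped with a warning rather than modelled.
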