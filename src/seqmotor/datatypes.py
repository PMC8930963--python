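"""Core in-memory containers shared by the simulation, scoring, cleaning,
centrality and inference stages.

Conventions
-----------
* Force traces are stored in % of the participant's maximum voluntary pinch
  force; the visual display maps 5 % to the bottom and 30 % to the top of the
  reference bar by default.
* Volumetric data are plain ``numpy`` arrays in (x, y, z[, t]) order with an
  isotropic voxel size in mm and the repetition time (TR) in seconds.
* Centrality maps are nonnegative with unit Euclidean norm over in-mask
  voxels; out-of-mask voxels are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

DAYS_BEHAVIOUR = ("d1", "d2", "d3", "d4", "d5", "d17")
DAYS_SCANNED = ("d0", "d1", "d2", "d5", "d17")
GROUPS = ("LRN", "SMP")
CONDITIONS = ("LRN", "SMP", "RST")


@dataclass
class ForceTrace:
    """One trial's uniformly sampled force curve (REF or FOR).

    Parameters
    ----------
    samples : 1-D array of force values in % of maximum voluntary force.
    fs : sampling rate in Hz.
    force_range : optional (lo, hi) display range the trace must stay in.
    """

    samples: np.ndarray
    fs: float
    force_range: tuple[float, float] | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InvalidArgumentError("samples must be a 1-D array with >= 2 points")
        if not self.fs > 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        if self.force_range is not None:
            lo, hi = self.force_range
            if not lo < hi:
                raise InvalidArgumentError("force_range must satisfy lo < hi")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class SequencePair:
    """A learning (LRN) reference sequence and its matched sinusoidal control
    (SMP), with the per-constraint relative deviations of the match."""

    lrn_ref: ForceTrace
    smp_ref: ForceTrace
    match_report: dict[str, float]

    def __post_init__(self):
        if self.lrn_ref.fs != self.smp_ref.fs:
            raise InvalidArgumentError("LRN and SMP references must share fs")
        if self.lrn_ref.n_samples != self.smp_ref.n_samples:
            raise InvalidArgumentError("LRN and SMP references must share duration")


@dataclass
class BehaviourGroundTruth:
    """Planted parameters behind a simulated behavioural cohort."""

    planted_lag_ms: "pandas.DataFrame"  # noqa: F821 - columns subject/day/block/trial/condition/lag_ms
    planted_noise_sd: float
    group_assignment: dict[str, str]


@dataclass
class BOLDDataset:
    """A 4-D BOLD acquisition with its masks and (optionally) motion traces."""

    data: np.ndarray
    tr: float
    voxel_size: float
    brain_mask: np.ndarray
    wm_mask: np.ndarray | None = None
    csf_mask: np.ndarray | None = None
    motion_params: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidArgumentError("BOLD data must be 4-D (x, y, z, t)")
        if self.data.shape[3] < 2:
            raise InvalidArgumentError("need at least 2 volumes")
        if not self.tr > 0:
            raise InvalidArgumentError("TR must be positive")
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise InvalidArgumentError("brain mask shape must match the grid")
        if not self.brain_mask.any():
            raise InvalidArgumentError("brain mask is empty")
        for name in ("wm_mask", "csf_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m).astype(bool)
                if m.shape != self.data.shape[:3]:
                    raise InvalidArgumentError(f"{name} shape must match the grid")
                setattr(self, name, m)
        masks = [m for m in (self.brain_mask, self.wm_mask, self.csf_mask) if m is not None]
        total = sum(m.astype(int) for m in masks)
        if (total > 1).any():
            raise InvalidArgumentError("brain/WM/CSF masks must be mutually disjoint")
        if self.motion_params is not None:
            self.motion_params = np.asarray(self.motion_params, dtype=float)
            if self.motion_params.shape != (self.n_volumes, 6):
                raise InvalidArgumentError("motion_params must be (n_volumes, 6)")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size] * 3 + [1.0])

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class PhantomGroundTruth:
    """Planted structure of a simulated BOLD cohort: labelled regions, the
    per-session region-by-region target correlation matrices and the region
    carrying the group-by-time centrality effect."""

    region_masks: dict[str, np.ndarray]
    region_order: list[str]
    session_correlation: dict[tuple[str, str], np.ndarray]
    effect_region: str


@dataclass
class ConfoundMatrix:
    """Named nuisance regressors; thin wrapper over a DataFrame."""

    table: "pandas.DataFrame"  # noqa: F821

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def n_rows(self) -> int:
        return len(self.table)


@dataclass
class CleanedBOLD:
    """Nuisance-cleaned, band-limited, variance-normalized BOLD data."""

    data: np.ndarray
    tr: float
    voxel_size: float
    mask: np.ndarray
    provenance: list[dict] = field(default_factory=list)
    affine: np.ndarray | None = None

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class ECMap:
    """Per-voxel eigenvector centrality of the voxelwise similarity graph.

    ``values`` is a 3-D array, zero outside ``mask``; in-mask values are
    nonnegative with unit Euclidean norm.
    """

    values: np.ndarray
    mask: np.ndarray
    iterations: int
    converged: bool
    eigenvalue_estimate: float

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class ECDelta:
    """Voxelwise centrality change of one subject between two sessions."""

    values: np.ndarray
    mask: np.ndarray
    day_pair: tuple[str, str]


@dataclass
class TrialScore:
    syn_ms: float
    rmse: float
    peak_corr: float


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_sq: float
    epsilon: float | None = None
    correction: str = "none"
    mauchly_W: float | None = None
    mauchly_p: float | None = None


@dataclass(frozen=True)
class StageContrast:
    """One of the 8 directional learning-stage contrasts."""

    name: str
    day_pair: tuple[str, str]
    direction: str  # "decrease" or "increase" (relative to the LRN group)

    def __post_init__(self):
        if self.direction not in ("decrease", "increase"):
            raise InvalidArgumentError("direction must be 'decrease' or 'increase'")


STAGE_DAY_PAIRS: dict[str, tuple[str, str]] = {
    "fast": ("d1", "d2"),
    "slow": ("d2", "d5"),
    "overall": ("d1", "d5"),
    "retention": ("d5", "d17"),
}


def stage_contrasts() -> list[StageContrast]:
    """The 4 learning stages x 2 directions = 8 interaction contrasts."""
    return [
        StageContrast(name, pair, direction)
        for name, pair in STAGE_DAY_PAIRS.items()
        for direction in ("decrease", "increase")
    ]


@dataclass
class TMap:
    t: np.ndarray
    df: int
    mask: np.ndarray
    contrast: StageContrast | None = None


@dataclass
class ClusterResult:
    label: int
    size: int
    peak_t: float
    peak_coordinate: tuple[int, int, int]
    p_uncorrected: float
    q_fdr: float
    mask: np.ndarray | None = None


@dataclass
class GroupTrajectory:
    """Per-group, per-day mean EC within an ROI plus the stage change
    summary (mean, SEM, t-based 95% CI)."""

    roi: np.ndarray
    days: list[str]
    per_day: dict[str, "pandas.DataFrame"]  # noqa: F821 - group -> day stats
    change: dict[str, dict]  # group -> {mean, sem, ci95, n}
    day_pair: tuple[str, str]


@dataclass
class SpecificityVerdict:
    driving_group: str  # LRN | SMP | none | both
    sequence_specific: bool
    rationale: dict

    def __post_init__(self):
        if self.sequence_specific and self.driving_group != "LRN":
            raise InvalidArgumentError(
                "a sequence-specific effect must be driven by the LRN group"
            )
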