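"""Resting-state BOLD time-series cleaning.

The cleaning chain mirrors a standard confound-regression pipeline for
resting-state data: discard initial non-steady-state volumes, build a
nuisance matrix (12 motion regressors = 6 parameters plus first
derivatives, one-hot spike regressors from composite-motion / global-signal
outliers, and aCompCor-style high-variance components from white matter and
CSF), regress it out voxelwise, detrend, bandpass to the 0.01-0.1 Hz
resting-state band (order-4 Butterworth, applied forward-backward so the
phase is zero), re-standardize so every in-mask voxel has exactly zero mean
and unit variance, and finally smooth spatially with a mask-aware Gaussian
kernel (2.4 mm FWHM by default).

Rotational motion is converted to millimetres on a 50 mm sphere when
computing composite motion, a common convention for head-sized geometry.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from nilearn.signal import high_variance_confounds as _nilearn_hvc
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, detrend as _detrend, filtfilt

from .datatypes import BOLDDataset, CleanedBOLD, ConfoundMatrix
from .errors import InvalidArgumentError

__all__ = [
    "drop_initial_volumes",
    "high_variance_confounds",
    "detect_spikes",
    "build_confound_matrix",
    "clean_timeseries",
    "smooth_gaussian",
    "preprocess_bold",
]

ROTATION_RADIUS_MM = 50.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def drop_initial_volumes(bold: BOLDDataset, n: int = 5) -> BOLDDataset:
    """Remove the first ``n`` volumes (signal stabilization) and trim the
    motion parameters to match."""
    if n < 0 or n >= bold.n_volumes:
        raise InvalidArgumentError(
            f"n must be in [0, {bold.n_volumes - 1}], got {n}"
        )
    if n == 0:
        return bold
    return BOLDDataset(
        data=bold.data[..., n:],
        tr=bold.tr,
        voxel_size=bold.voxel_size,
        brain_mask=bold.brain_mask,
        wm_mask=bold.wm_mask,
        csf_mask=bold.csf_mask,
        motion_params=None if bold.motion_params is None else bold.motion_params[n:],
        affine=bold.affine,
    )


def high_variance_confounds(
    bold: BOLDDataset,
    tissue_mask: np.ndarray,
    n_components: int = 5,
    variance_percentile: float = 2.0,
    prefix: str = "compcor",
) -> pd.DataFrame:
    """aCompCor-style physiological confounds from a tissue compartment.

    The top ``variance_percentile`` % most variable voxels in the mask are
    detrended and the first ``n_components`` left singular vectors of their
    time x voxel matrix are returned as orthonormal confound columns.
    """
    tissue_mask = np.asarray(tissue_mask).astype(bool)
    if not tissue_mask.any():
        raise InvalidArgumentError("tissue mask is empty")
    series = bold.data[tissue_mask].T  # time x voxels
    n_vox = series.shape[1]
    if n_vox < n_components:
        warnings.warn(
            f"only {n_vox} voxels in mask; reducing components from {n_components}",
            stacklevel=2,
        )
        n_components = n_vox
    comps = _nilearn_hvc(
        series, n_confounds=n_components, percentile=variance_percentile, detrend=True
    )
    cols = {f"{prefix}_{i + 1:02d}": comps[:, i] for i in range(comps.shape[1])}
    return pd.DataFrame(cols)


def composite_motion(motion_params: np.ndarray, radius_mm: float = ROTATION_RADIUS_MM) -> np.ndarray:
    """Frame-to-frame composite head displacement (mm); rotations are
    converted to arc length on a sphere of ``radius_mm``."""
    motion_params = np.asarray(motion_params, dtype=float)
    diffs = np.diff(motion_params, axis=0, prepend=motion_params[:1])
    diffs = diffs.copy()
    diffs[:, 3:] *= radius_mm
    return np.linalg.norm(diffs, axis=1)


def detect_spikes(
    motion_params: np.ndarray | None,
    global_signal: np.ndarray,
    motion_z: float = 3.0,
    signal_z: float = 3.0,
) -> pd.DataFrame:
    """Flag volumes whose composite motion or global brain signal is an
    outlier (|z| above threshold); returns one one-hot column per flagged
    volume (possibly none)."""
    global_signal = np.asarray(global_signal, dtype=float)
    n = global_signal.size
    flagged = np.zeros(n, dtype=bool)

    def zscores(x):
        sd = x.std()
        return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd

    if motion_params is not None:
        cm = composite_motion(motion_params)
        flagged |= np.abs(zscores(cm)) > motion_z
    flagged |= np.abs(zscores(global_signal)) > signal_z
    cols = {}
    for idx in np.flatnonzero(flagged):
        col = np.zeros(n)
        col[idx] = 1.0
        cols[f"spike_{idx:04d}"] = col
    return pd.DataFrame(cols, index=range(n))


def build_confound_matrix(
    bold: BOLDDataset,
    n_compcor: int = 5,
    variance_percentile: float = 2.0,
    motion_z: float = 3.0,
    signal_z: float = 3.0,
) -> ConfoundMatrix:
    """Assemble the full nuisance matrix: 12 motion regressors (6 parameters
    + first derivatives), spike indicators and per-tissue aCompCor
    components."""
    parts = []
    if bold.motion_params is not None:
        mp = bold.motion_params
        names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        motion = pd.DataFrame(mp, columns=names)
        deriv = motion.diff().fillna(0.0)
        deriv.columns = [f"{c}_derivative" for c in names]
        parts += [motion, deriv]
    gs = bold.data[bold.brain_mask].mean(axis=0)
    spikes = detect_spikes(bold.motion_params, gs, motion_z, signal_z)
    if not spikes.empty:
        parts.append(spikes.reset_index(drop=True))
    for tissue, mask in (("wm", bold.wm_mask), ("csf", bold.csf_mask)):
        if mask is not None and mask.any():
            parts.append(
                high_variance_confounds(
                    bold, mask, n_compcor, variance_percentile, prefix=f"compcor_{tissue}"
                )
            )
    if not parts:
        table = pd.DataFrame(index=range(bold.n_volumes))
    else:
        table = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    # drop all-zero columns (dead regressors)
    keep = [c for c in table.columns if np.any(table[c].to_numpy() != 0)]
    return ConfoundMatrix(table=table[keep])


def _drop_collinear(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that are linearly dependent on earlier ones."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < x.shape[1]:
        dropped = [names[j] for j in range(x.shape[1]) if j not in keep]
        warnings.warn(f"dropping collinear confound columns: {dropped}", stacklevel=3)
    return x[:, keep], [names[j] for j in keep]


def clean_timeseries(
    bold: BOLDDataset,
    confounds: ConfoundMatrix | pd.DataFrame | None = None,
    band: tuple[float, float] = (0.01, 0.1),
    filter_order: int = 4,
) -> CleanedBOLD:
    """Nuisance-clean all in-mask voxel timecourses.

    Steps, in order: confound regression (OLS residuals, intercept always
    included), linear detrend, variance normalization, zero-phase bandpass,
    and a final re-standardization so the output contract (zero mean, unit
    variance per in-mask voxel) holds exactly. Voxels left with (near) zero
    variance — e.g. a voxel equal to a confound — are flagged degenerate
    and removed from the output mask.
    """
    if isinstance(confounds, pd.DataFrame):
        confounds = ConfoundMatrix(table=confounds)
    t = bold.n_volumes
    lo, hi = band
    fs = 1.0 / bold.tr
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise InvalidArgumentError(
            f"band {band} must satisfy 0 < lo < hi < Nyquist ({nyq:.3f} Hz)"
        )

    mask = bold.brain_mask.copy()
    y = bold.data[mask].T.astype(float)  # time x voxels
    provenance = []

    if confounds is not None and confounds.table.shape[1] > 0:
        if confounds.n_rows != t:
            raise InvalidArgumentError(
                f"confound rows ({confounds.n_rows}) != volumes ({t})"
            )
        x = np.column_stack([np.ones(t), confounds.values])
        names = ["intercept"] + list(confounds.table.columns)
        x, kept = _drop_collinear(x, names)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        y = y - x @ beta
        provenance.append({"step": "confound_regression", "n_regressors": len(kept)})

    y = _detrend(y, axis=0, type="linear")
    provenance.append({"step": "detrend", "type": "linear"})

    sd = y.std(axis=0)
    degenerate = sd < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} voxel(s) degenerate after regression; removed from mask",
            stacklevel=2,
        )
    y[:, ~degenerate] /= sd[~degenerate]
    provenance.append({"step": "variance_normalize"})

    b, a = butter(filter_order, [lo / nyq, hi / nyq], btype="band")
    y = filtfilt(b, a, y, axis=0)
    provenance.append(
        {"step": "bandpass", "band_hz": [lo, hi], "order": filter_order, "zero_phase": True}
    )

    # final standardization: the unit-variance output contract
    y -= y.mean(axis=0)
    sd2 = y.std(axis=0)
    degenerate |= sd2 < 1e-12
    y[:, ~degenerate] /= sd2[~degenerate]
    provenance.append({"step": "restandardize"})

    out = np.zeros_like(bold.data)
    flat_idx = np.flatnonzero(mask.reshape(-1))
    out.reshape(-1, t)[flat_idx[~degenerate]] = y[:, ~degenerate].T
    new_mask = mask.reshape(-1).copy()
    new_mask[flat_idx[degenerate]] = False
    return CleanedBOLD(
        data=out,
        tr=bold.tr,
        voxel_size=bold.voxel_size,
        mask=new_mask.reshape(mask.shape),
        provenance=provenance,
        affine=bold.affine,
    )


def smooth_gaussian(
    data: np.ndarray | CleanedBOLD,
    fwhm_mm: float = 2.4,
    voxel_size: float | None = None,
    mask: np.ndarray | None = None,
):
    """Mask-aware 3-D Gaussian smoothing of each volume.

    The smoothed data are renormalized by the smoothed mask so intensities
    near the mask edge are not dimmed. ``fwhm_mm = 0`` is the identity.
    """
    if isinstance(data, CleanedBOLD):
        cleaned = data
        arr, voxel_size = cleaned.data, cleaned.voxel_size
        mask = cleaned.mask if mask is None else mask
    else:
        cleaned, arr = None, np.asarray(data, dtype=float)
        if voxel_size is None:
            raise InvalidArgumentError("voxel_size required for raw arrays")
    if fwhm_mm < 0:
        raise InvalidArgumentError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return data
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size
    if mask is None:
        mask = np.ones(arr.shape[:3], dtype=bool)
    m = mask.astype(float)
    sm_mask = gaussian_filter(m, sigma_vox)
    out = np.zeros_like(arr)
    with np.errstate(invalid="ignore", divide="ignore"):
        for v in range(arr.shape[3]):
            sm = gaussian_filter(arr[..., v] * m, sigma_vox)
            vol = np.where(sm_mask > 1e-12, sm / np.maximum(sm_mask, 1e-12), 0.0)
            out[..., v] = np.where(mask, vol, 0.0)
    if cleaned is not None:
        prov = cleaned.provenance + [{"step": "smooth", "fwhm_mm": fwhm_mm}]
        return CleanedBOLD(
            data=out,
            tr=cleaned.tr,
            voxel_size=cleaned.voxel_size,
            mask=cleaned.mask,
            provenance=prov,
            affine=cleaned.affine,
        )
    return out


def preprocess_bold(
    bold: BOLDDataset,
    n_drop: int = 5,
    band: tuple[float, float] = (0.01, 0.1),
    fwhm_mm: float = 2.4,
    n_compcor: int = 5,
    motion_z: float = 3.0,
    signal_z: float = 3.0,
) -> CleanedBOLD:
    """Full cleaning chain: drop volumes, confounds, clean, smooth."""
    bold = drop_initial_volumes(bold, n_drop)
    confounds = build_confound_matrix(
        bold, n_compcor=n_compcor, motion_z=motion_z, signal_z=signal_z
    )
    cleaned = clean_timeseries(bold, confounds, band=band)
    cleaned.provenance.insert(0, {"step": "drop_initial_volumes", "n": n_drop})
    return smooth_gaussian(cleaned, fwhm_mm=fwhm_mm)
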