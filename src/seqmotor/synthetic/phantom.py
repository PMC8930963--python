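"""4-D BOLD phantom generator with planted region-structured connectivity.

The phantom emulates the statistical structure the interaction analysis
assumes: a two-group longitudinal cohort in which every subject-session is a
4-D volume whose in-brain voxels load on latent region signals. Region
latents are band-limited (0.01-0.1 Hz, so the cleaning stage does not
destroy them) and are mixed to realize a per-(group, day) target
region-by-region correlation matrix; an *effect specification* ramps one
region's coupling to the hub across sessions in exactly one group, which is
what plants a group-by-time eigenvector-centrality effect.

The latent mixing uses an empirical-whitening + matrix-square-root
transform, so the realized latent correlation matrix equals the target
exactly for every finite series; region-mean empirical correlations then
deviate only through voxel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from ..datatypes import BOLDDataset, DAYS_SCANNED, PhantomGroundTruth
from ..errors import InvalidArgumentError

__all__ = [
    "RegionSpec",
    "EffectSpec",
    "NoiseSpec",
    "default_region_spec",
    "default_effect_spec",
    "gen_bold_cohort",
]


@dataclass(frozen=True)
class RegionSpec:
    """A spherical region: center and radius as fractions of the grid."""

    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class EffectSpec:
    """The planted group-by-time effect: in ``group``, the coupling of
    ``region`` to the hub follows ``ramp`` (day -> correlation) instead of
    the baseline coupling."""

    region: str = "regionA"
    group: str = "LRN"
    ramp: dict = field(
        default_factory=lambda: {"d0": 0.6, "d1": 0.6, "d2": 0.45, "d5": 0.2, "d17": 0.2}
    )


@dataclass(frozen=True)
class NoiseSpec:
    voxel_noise_sd: float = 0.45
    loading_mean: float = 1.0
    loading_sd: float = 0.1
    drift_max: float = 0.0
    physio_amp: float = 1.0  # WM/CSF structured-noise amplitude
    motion_walk_sd: float = 0.005  # mm (or rad) per step of the random walk


def default_region_spec() -> dict[str, RegionSpec]:
    """Four disjoint spherical regions inside the brain: a central hub and
    three satellites."""
    return {
        "hub": RegionSpec((0.50, 0.50, 0.50), 0.12),
        "regionA": RegionSpec((0.76, 0.50, 0.50), 0.10),
        "regionB": RegionSpec((0.24, 0.50, 0.50), 0.10),
        "regionC": RegionSpec((0.50, 0.76, 0.50), 0.10),
    }


def default_effect_spec() -> EffectSpec:
    return EffectSpec()


def _sphere(grid_shape, center_frac, radius_frac) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    n = min(grid_shape)
    center = [c * (s - 1) for c, s in zip(center_frac, grid_shape)]
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= (radius_frac * n) ** 2


def _radial_taper(mask: np.ndarray, spec: RegionSpec | None, grid_shape) -> np.ndarray:
    """Loading taper from 1 at a region's center to 0.3 at its boundary;
    filler parcels (no RegionSpec) are untapered."""
    if spec is None:
        return np.ones(int(mask.sum()))
    idx = np.argwhere(mask).astype(float)
    center = np.array([c * (s - 1) for c, s in zip(spec.center, grid_shape)])
    r = spec.radius * min(grid_shape)
    d = np.linalg.norm(idx - center, axis=1) / max(r, 1e-9)
    return 1.0 - 0.7 * np.clip(d, 0.0, 1.0)


def _shell(grid_shape, r_in_frac, r_out_frac) -> np.ndarray:
    idx = np.indices(grid_shape, dtype=float)
    n = min(grid_shape)
    center = [(s - 1) / 2.0 for s in grid_shape]
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return ((r_in_frac * n) ** 2 < d2) & (d2 <= (r_out_frac * n) ** 2)


def _band_limited_noise(rng, n_series, n_volumes, tr, band=(0.01, 0.1)) -> np.ndarray:
    """Independent unit-variance band-limited series, shape (T, k)."""
    fs = 1.0 / tr
    b, a = butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="band")
    x = rng.standard_normal((n_volumes, n_series))
    x = filtfilt(b, a, x, axis=0)
    x -= x.mean(axis=0)
    x /= x.std(axis=0)
    return x


def _mix_to_correlation(raw: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Linearly transform independent series so their *empirical* correlation
    matrix equals ``corr`` exactly (whiten, then multiply by a symmetric
    square root)."""
    t, k = raw.shape
    x = raw - raw.mean(axis=0)
    # empirical whitening via SVD: columns become exactly orthonormal
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    white = u @ vt * np.sqrt(t)
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise InvalidArgumentError("correlation matrix is not positive semidefinite")
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
    return white @ root


def _session_correlation_matrix(
    region_order: list[str],
    base_hub_corr: float,
    hub_corr_overrides: dict[str, float],
    filler_hub_corr: float = 0.3,
) -> np.ndarray:
    """Single-factor structure: every satellite couples to the hub with its
    own rho, satellites inter-correlate as rho_i * rho_j (always PSD)."""
    rho = {
        r: hub_corr_overrides.get(
            r, filler_hub_corr if r.startswith("filler") else base_hub_corr
        )
        for r in region_order
        if r != "hub"
    }
    k = len(region_order)
    corr = np.eye(k)
    for i, ri in enumerate(region_order):
        for j, rj in enumerate(region_order):
            if i == j:
                continue
            if ri == "hub":
                corr[i, j] = rho[rj]
            elif rj == "hub":
                corr[i, j] = rho[ri]
            else:
                corr[i, j] = rho[ri] * rho[rj]
    return corr


def gen_bold_cohort(
    grid_shape: tuple[int, int, int] = (20, 20, 20),
    n_per_group: int = 10,
    days: tuple[str, ...] = DAYS_SCANNED,
    n_volumes: int = 300,
    tr: float = 1.13,
    voxel_size: float = 2.4,
    region_spec: dict[str, RegionSpec] | None = None,
    effect_spec: EffectSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    base_hub_corr: float = 0.6,
    filler_hub_corr: float = 0.3,
    fill_background: bool = True,
    filler_block: int = 3,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], BOLDDataset], PhantomGroundTruth]:
    """Simulate a longitudinal two-group BOLD phantom cohort.

    Returns a dict mapping ``(subject, day)`` to a :class:`BOLDDataset` and
    the :class:`PhantomGroundTruth` (region masks, per-session target
    correlation matrices, effect region).
    """
    if n_volumes < 50:
        raise InvalidArgumentError("need at least 50 volumes for stable correlations")
    region_spec = region_spec or default_region_spec()
    effect_spec = effect_spec if effect_spec is not None else default_effect_spec()
    noise = noise_spec or NoiseSpec()
    if len(region_spec) < 3:
        raise InvalidArgumentError("need at least 3 regions")
    if effect_spec.region not in region_spec:
        raise InvalidArgumentError(f"effect region {effect_spec.region!r} not in region_spec")

    brain_mask = _sphere(grid_shape, (0.5, 0.5, 0.5), 0.34)
    wm_mask = _shell(grid_shape, 0.36, 0.42)
    csf_mask = _shell(grid_shape, 0.44, 0.48)

    region_masks = {
        name: _sphere(grid_shape, rs.center, rs.radius) & brain_mask
        for name, rs in region_spec.items()
    }
    flat = np.zeros(grid_shape, dtype=int)
    for m in region_masks.values():
        flat += m.astype(int)
    if (flat > 1).any():
        raise InvalidArgumentError("region masks overlap")

    # tile the remaining brain into small cubic "filler" parcels so every
    # brain voxel carries region-structured signal (weakly hub-coupled);
    # this emulates whole-brain parcellated connectivity rather than
    # leaving unstructured-noise voxels, while keeping each filler small
    # enough that chance fluctuations stay local
    if fill_background:
        leftover = brain_mask & ~(flat > 0)
        idx = np.indices(grid_shape)
        b = filler_block
        cell = (
            (idx[0] // b)
            + (idx[1] // b) * (grid_shape[0] // b + 1)
            + (idx[2] // b) * (grid_shape[0] // b + 1) ** 2
        )
        k = 0
        for c in np.unique(cell[leftover]):
            m = leftover & (cell == c)
            if m.any():
                k += 1
                region_masks[f"filler{k:03d}"] = m
                flat += m.astype(int)

    region_order = list(region_masks)
    session_corr: dict[tuple[str, str], np.ndarray] = {}
    for group in ("LRN", "SMP"):
        for day in days:
            overrides = {}
            if group == effect_spec.group and day in effect_spec.ramp:
                overrides[effect_spec.region] = effect_spec.ramp[day]
            corr = _session_correlation_matrix(
                region_order, base_hub_corr, overrides, filler_hub_corr
            )
            w = np.linalg.eigvalsh(corr)
            if w.min() < -1e-10:
                raise InvalidArgumentError(
                    f"requested correlation matrix for ({group}, {day}) is not PSD"
                )
            session_corr[(group, day)] = corr

    root = np.random.default_rng(seed)
    subjects = [(f"lrn{i + 1:02d}", "LRN") for i in range(n_per_group)] + [
        (f"smp{i + 1:02d}", "SMP") for i in range(n_per_group)
    ]

    background = brain_mask & ~(flat > 0)
    datasets: dict[tuple[str, str], BOLDDataset] = {}
    for subject, group in subjects:
        sub_rng = np.random.default_rng(root.integers(2**31))
        # per-subject, session-stable voxel loadings
        # session-stable voxel loadings with a radial taper: voxels near the
        # region boundary couple more weakly to the region latent, giving
        # graded (rather than all-or-nothing) connectivity profiles
        loadings = {}
        for name, m in region_masks.items():
            base = np.abs(sub_rng.normal(noise.loading_mean, noise.loading_sd, int(m.sum())))
            loadings[name] = base * _radial_taper(m, region_spec.get(name), grid_shape)
        for day in days:
            rng = np.random.default_rng(sub_rng.integers(2**31))
            raw = _band_limited_noise(rng, len(region_order), n_volumes, tr)
            latents = _mix_to_correlation(raw, session_corr[(group, day)])
            data = np.zeros(grid_shape + (n_volumes,), dtype=float)
            for k, name in enumerate(region_order):
                m = region_masks[name]
                sig = loadings[name][:, None] * latents[:, k][None, :]
                data[m] = sig + rng.normal(0, noise.voxel_noise_sd, sig.shape)
            nb = int(background.sum())
            if nb:
                data[background] = rng.normal(0, 1.0, (nb, n_volumes))
            if noise.drift_max > 0:
                ramp = np.linspace(-0.5, 0.5, n_volumes)
                amp = rng.uniform(-noise.drift_max, noise.drift_max, int(brain_mask.sum()))
                data[brain_mask] += amp[:, None] * ramp[None, :]
            # WM / CSF: shared structured "physiological" components + noise
            tt = np.arange(n_volumes) * tr
            for tissue_mask, freq in ((wm_mask, 0.03), (csf_mask, 0.07)):
                nt = int(tissue_mask.sum())
                if nt == 0:
                    continue
                physio = np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
                load = np.abs(rng.normal(noise.physio_amp, 0.1, nt))
                data[tissue_mask] = (
                    load[:, None] * physio[None, :]
                    + rng.normal(0, noise.voxel_noise_sd, (nt, n_volumes))
                )
            motion = np.cumsum(
                rng.normal(0, noise.motion_walk_sd, (n_volumes, 6)), axis=0
            )
            datasets[(subject, day)] = BOLDDataset(
                data=data,
                tr=tr,
                voxel_size=voxel_size,
                brain_mask=brain_mask,
                wm_mask=wm_mask,
                csf_mask=csf_mask,
                motion_params=motion,
            )

    truth = PhantomGroundTruth(
        region_masks=region_masks,
        region_order=region_order,
        session_correlation=session_corr,
        effect_region=effect_spec.region,
    )
    return datasets, truth
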