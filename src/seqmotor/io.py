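"""File formats: NIfTI-1 volumes (with TR in the header), force-trace and
cohort TSVs, EC-map sidecars and JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import BOLDDataset, ECMap, ForceTrace
from .errors import InvalidArgumentError

__all__ = [
    "write_bold",
    "read_bold",
    "write_mask",
    "read_mask",
    "write_ecmap",
    "read_ecmap",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_json",
]


def write_bold(bold: BOLDDataset, path: str | Path) -> Path:
    """Write a 4-D BOLD dataset as NIfTI-1 (float32), TR in the header."""
    path = Path(path)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms((bold.voxel_size,) * 3 + (bold.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def read_bold(
    path: str | Path,
    brain_mask: np.ndarray | str | Path,
    wm_mask=None,
    csf_mask=None,
    motion_params: np.ndarray | str | Path | None = None,
) -> BOLDDataset:
    """Load a 4-D NIfTI plus masks into a :class:`BOLDDataset`.

    The TR is read from the header's fourth zoom; a 3-D file or a zero TR
    is a format error.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise InvalidArgumentError(f"{path}: expected a 4-D volume, got {img.ndim}-D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3])
    if not tr > 0:
        raise InvalidArgumentError(f"{path}: repetition time missing from header")
    voxel_size = float(zooms[0])

    def _mask(m):
        if m is None:
            return None
        if isinstance(m, (str, Path)):
            return np.asarray(nib.load(str(m)).get_fdata()) > 0.5
        return np.asarray(m).astype(bool)

    if isinstance(motion_params, (str, Path)):
        motion_params = pd.read_csv(motion_params, sep="\t").to_numpy(dtype=float)
    return BOLDDataset(
        data=np.asarray(img.get_fdata(), dtype=float),
        tr=tr,
        voxel_size=voxel_size,
        brain_mask=_mask(brain_mask),
        wm_mask=_mask(wm_mask),
        csf_mask=_mask(csf_mask),
        motion_params=motion_params,
        affine=np.asarray(img.affine),
    )


def write_mask(mask: np.ndarray, path: str | Path, voxel_size: float = 1.0) -> Path:
    path = Path(path)
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def write_ecmap(ecmap: ECMap, path: str | Path, voxel_size: float = 1.0) -> Path:
    """EC map as float32 NIfTI + JSON sidecar with run diagnostics."""
    path = Path(path)
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(ecmap.values.astype(np.float32), affine), path)
    sidecar = {
        "iterations": ecmap.iterations,
        "converged": bool(ecmap.converged),
        "eigenvalue_estimate": ecmap.eigenvalue_estimate,
    }
    side_path = path.with_suffix("").with_suffix("") if path.suffix == ".gz" else path
    Path(str(side_path).replace(".nii", "") + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    return path


def read_ecmap(path: str | Path) -> ECMap:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=float)
    side = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return ECMap(
        values=values,
        mask=values != 0,
        iterations=meta.get("iterations", -1),
        converged=meta.get("converged", True),
        eigenvalue_estimate=meta.get("eigenvalue_estimate", float("nan")),
    )


def write_trace_tsv(ref: ForceTrace, force: ForceTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": ref.times, "ref": ref.samples, "force": force.samples})
    df.to_csv(path, sep="\t", index=False)
    return path


def read_trace_tsv(path: str | Path) -> tuple[ForceTrace, ForceTrace]:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "ref", "force"):
        if col not in df.columns:
            raise InvalidArgumentError(f"{path}: missing column {col!r}")
    dt = np.diff(df["time_s"].to_numpy())
    if dt.size == 0 or not np.allclose(dt, dt[0]):
        raise InvalidArgumentError(f"{path}: non-uniform sampling")
    fs = 1.0 / dt[0]
    ref = ForceTrace(df["ref"].to_numpy(), fs=fs)
    force = ForceTrace(df["force"].to_numpy(), fs=fs)
    return ref, force


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=default))
    return path
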