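"""Pipeline configuration and run logging."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "RunLog"]


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end pipeline.

    Defaults follow the study protocol where one is stated (primary
    threshold p < 0.001, cluster-level FDR 0.05, 0.01-0.1 Hz band, 2.4 mm
    FWHM, 5 dropped volumes, TR 1.13 s) and desk-scale phantom sizes
    otherwise.
    """

    seed: int = 0
    # behavioural simulation
    n_per_group_behaviour: int = 6
    # phantom simulation
    grid_shape: tuple = (16, 16, 16)
    n_per_group_bold: int = 6
    n_volumes: int = 120
    tr: float = 1.13
    voxel_size: float = 1.2
    scan_days: tuple = ("d0", "d1", "d2", "d5", "d17")
    # cleaning
    n_drop: int = 5
    band: tuple = (0.01, 0.1)
    fwhm_mm: float = 2.4
    n_compcor: int = 5
    # centrality
    ecm_tol: float = 1e-9
    ecm_max_iter: int = 1000
    similarity: str = "add1half"
    # inference
    primary_p: float = 0.001
    cluster_alpha: float = 0.05
    n_perm: int = 200
    connectivity: int = 18
    # paths
    out_dir: str = "seqmotor_out"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        # YAML round-trips tuples as lists; normalize back
        cfg.grid_shape = tuple(cfg.grid_shape)
        cfg.scan_days = tuple(cfg.scan_days)
        cfg.band = tuple(cfg.band)
        return cfg


def _digest(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, np.ndarray):
        h.update(np.ascontiguousarray(obj).tobytes())
    elif isinstance(obj, Path):
        h.update(obj.read_bytes() if obj.exists() else str(obj).encode())
    elif isinstance(obj, str):
        h.update(obj.encode())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


@dataclass
class RunLog:
    """Ordered record of pipeline steps with parameter and data digests."""

    records: list = field(default_factory=list)

    def append(self, name: str, parameters: dict, inputs=None, outputs=None, wall_s=None):
        self.records.append(
            dict(
                name=name,
                parameters=parameters,
                input_digest=None if inputs is None else _digest(inputs),
                output_digest=None if outputs is None else _digest(outputs),
                wall_s=wall_s,
                timestamp=time.time(),
            )
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.records, indent=2, default=str))
        return path
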