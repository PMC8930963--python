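"""Small block-correlated random phantoms for exercising the centrality
code on varied correlation structure (irregular masks, variable block
counts, near-degenerate spectra)."""

from __future__ import annotations

import numpy as np

__all__ = ["gen_block_phantom"]


def gen_block_phantom(
    rng: np.random.Generator,
    n_voxels_target: int = 200,
    n_volumes: int = 120,
    n_blocks: int = 4,
    grid: tuple[int, int, int] = (8, 8, 8),
) -> tuple[np.ndarray, np.ndarray]:
    """A 4-D array whose in-mask voxels load on ``n_blocks`` latent series
    with random weights plus unit white noise; the mask is a random subset
    of the grid. Returns ``(data_4d, mask)``."""
    flat_n = int(np.prod(grid))
    k = min(n_voxels_target, flat_n)
    idx = rng.choice(flat_n, size=k, replace=False)
    mask = np.zeros(flat_n, dtype=bool)
    mask[idx] = True
    mask = mask.reshape(grid)
    latents = rng.standard_normal((n_blocks, n_volumes))
    assign = rng.integers(0, n_blocks, size=k)
    weight = rng.uniform(0.3, 1.5, size=k)
    series = weight[:, None] * latents[assign] + rng.standard_normal((k, n_volumes))
    data = np.zeros(grid + (n_volumes,))
    data[mask] = series
    return data, mask
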