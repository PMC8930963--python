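"""Voxelwise eigenvector centrality mapping (ECM).

Every in-mask voxel is a node of a weighted graph whose edge weights are a
similarity of the two voxels' cleaned timecourses. The centrality of a node
is its entry in the dominant eigenvector of the similarity matrix: a voxel
is central when it is similar to other central voxels.

Similarity is ``M = (C + 1) / 2`` with ``C`` the voxel-by-voxel Pearson
correlation matrix. The affine rescaling maps correlations into [0, 1], so
``M`` is strictly positive and the Perron-Frobenius theorem guarantees a
unique, entrywise-nonnegative dominant eigenvector — which is what licenses
plain power iteration from a positive start vector. An absolute-value
similarity ``|C|`` is available as an option (it loses the uniqueness
guarantee when the mask decomposes into uncorrelated blocks).

:func:`fast_ecm` never materializes the voxel-by-voxel matrix: with ``Z``
the voxel x time array of z-scored timecourses (so ``C = Z Z^T / T``), a
matrix-vector product is

    M v = ( Z (Z^T v) / T  +  1 * sum(v) ) / 2

which costs O(voxels x time) per iteration. :func:`dense_ecm` builds the
matrix explicitly and solves the symmetric eigenproblem; it is the oracle
for validating the matrix-free path on small masks.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CleanedBOLD, ECDelta, ECMap
from .errors import InvalidArgumentError

__all__ = ["fast_ecm", "dense_ecm", "ec_delta"]

_DENSE_GUARD = 5000


def _extract_z(data_4d: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score in-mask timecourses; drops zero-variance voxels from the mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InvalidArgumentError("mask is empty")
    z = data_4d[mask].astype(float)
    if z.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 volumes")
    mu = z.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    dead = sd[:, 0] < 1e-12
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance voxel(s) dropped from the mask",
            stacklevel=3,
        )
        new_mask = mask.copy()
        new_mask[tuple(np.argwhere(mask)[dead].T)] = False
        mask = new_mask
        z, mu, sd = z[~dead], mu[~dead], sd[~dead]
    if z.shape[0] == 0:
        raise InvalidArgumentError("no voxels with temporal variance in the mask")
    return (z - mu) / sd, mask


def _resolve(cleaned) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(cleaned, CleanedBOLD):
        return cleaned.data, cleaned.mask
    return np.asarray(cleaned, dtype=float), None


def fast_ecm(
    cleaned: CleanedBOLD | np.ndarray,
    mask: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 1000,
    similarity: str = "add1half",
) -> ECMap:
    """Matrix-free eigenvector centrality by power iteration.

    Iterates ``v <- M v / ||M v||`` from the uniform positive unit vector
    until the L2 change of the iterate falls below ``tol`` (or ``max_iter``
    is hit, in which case the map is returned with ``converged=False`` and
    a warning). The Rayleigh quotient of the final iterate estimates the
    dominant eigenvalue.
    """
    data, default_mask = _resolve(cleaned)
    mask = default_mask if mask is None else mask
    if mask is None:
        raise InvalidArgumentError("a mask is required for raw arrays")
    z, mask = _extract_z(data, mask)
    n, t = z.shape

    if similarity == "abs":
        # |C| admits no matrix-free product; materialize (guarded)
        if n > _DENSE_GUARD:
            raise InvalidArgumentError(
                f"similarity='abs' requires materializing the matrix; "
                f"mask has {n} > {_DENSE_GUARD} voxels"
            )
        m = np.abs(z @ z.T / t)
        matvec = lambda v: m @ v  # noqa: E731
    elif similarity == "add1half":
        matvec = lambda v: (z @ (z.T @ v) / t + v.sum()) / 2.0  # noqa: E731
    else:
        raise InvalidArgumentError("similarity must be 'add1half' or 'abs'")

    v = np.full(n, 1.0 / np.sqrt(n))
    converged = False
    iterations = 0
    mv = matvec(v)
    for iterations in range(1, max_iter + 1):
        v_new = mv / np.linalg.norm(mv)
        mv = matvec(v_new)
        if np.linalg.norm(v_new - v) < tol:
            v = v_new
            converged = True
            break
        v = v_new
    if not converged:
        warnings.warn(
            f"power iteration did not converge in {max_iter} iterations", stacklevel=2
        )
    rayleigh = float(v @ matvec(v))

    values = np.zeros(mask.shape)
    values[mask] = v
    return ECMap(
        values=values,
        mask=mask,
        iterations=iterations,
        converged=converged,
        eigenvalue_estimate=rayleigh,
    )


def dense_ecm(
    cleaned: CleanedBOLD | np.ndarray,
    mask: np.ndarray | None = None,
    similarity: str = "add1half",
) -> ECMap:
    """Dense eigendecomposition oracle: forms the similarity matrix and
    returns the eigenvector of its largest eigenvalue (sign-fixed to the
    nonnegative orthant, unit norm). Refuses masks above 5000 voxels."""
    data, default_mask = _resolve(cleaned)
    mask = default_mask if mask is None else mask
    if mask is None:
        raise InvalidArgumentError("a mask is required for raw arrays")
    z, mask = _extract_z(data, mask)
    n, t = z.shape
    if n > _DENSE_GUARD:
        raise InvalidArgumentError(
            f"mask has {n} voxels, above the dense guard of {_DENSE_GUARD}"
        )
    c = z @ z.T / t
    if similarity == "add1half":
        m = (c + 1.0) / 2.0
    elif similarity == "abs":
        m = np.abs(c)
    else:
        raise InvalidArgumentError("similarity must be 'add1half' or 'abs'")
    w, vecs = np.linalg.eigh(m)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v /= np.linalg.norm(v)
    values = np.zeros(mask.shape)
    values[mask] = v
    return ECMap(
        values=values,
        mask=mask,
        iterations=0,
        converged=True,
        eigenvalue_estimate=float(w[-1]),
    )


def ec_delta(map_a: ECMap, map_b: ECMap, day_pair: tuple[str, str] = ("a", "b")) -> ECDelta:
    """Voxelwise centrality change ``map_b - map_a`` on the intersection of
    the two masks."""
    if map_a.values.shape != map_b.values.shape:
        raise InvalidArgumentError("EC maps live on different grids")
    mask = map_a.mask & map_b.mask
    values = np.zeros_like(map_a.values)
    values[mask] = map_b.values[mask] - map_a.values[mask]
    return ECDelta(values=values, mask=mask, day_pair=tuple(day_pair))
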