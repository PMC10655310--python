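"""Low-dimensional ordination: classical (Torgerson) MDS and PCA.

Classical MDS double-centres the squared distance matrix,
B = -1/2 * J (D o D) J with J = I - 11'/n, and embeds with the top-k
non-negative eigenpairs as V * Lambda^(1/2).  It is deterministic and
exact for Euclidean distance matrices, unlike stress-minimising variants.

PCA decomposes the column-centred (optionally unit-scaled) haplogroup
frequency matrix by SVD; variance fractions over all axes sum to 1.

Coordinates are identified only up to rotation/reflection; for
reproducible output each axis is oriented so its largest-magnitude
loading (or coordinate, for MDS) is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen import DistanceMatrix

__all__ = ["OrdinationResult", "classical_mds", "pca"]


@dataclass
class OrdinationResult:
    """Embedding coordinates plus per-axis weights.

    ``coordinates``: labels x retained axes; ``eigenvalues``: the axis
    weights (MDS eigenvalues or PCA explained variances);
    ``variance_fractions``: weight of each axis relative to the total
    (PCA fractions over all axes sum to 1); ``loadings``: PCA variable
    loadings (None for MDS).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    method: str
    loadings: pd.DataFrame | None = None


def _orient(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip each axis so the largest-|reference| entry is positive."""
    signs = np.ones(coords.shape[1])
    for a in range(coords.shape[1]):
        col = reference[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            signs[a] = -1.0
    return coords * signs


def classical_mds(dist: DistanceMatrix | pd.DataFrame, k: int = 2) -> OrdinationResult:
    """Torgerson metric MDS of a symmetric zero-diagonal distance matrix."""
    if isinstance(dist, DistanceMatrix):
        labels, d = dist.labels, dist.values
    else:
        labels, d = list(dist.index), dist.to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(labels)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval[0]) if n else 0.0)
    n_pos = int(np.sum(eigval > tol))
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            f"truncating", stacklevel=2,
        )
        k = max(n_pos, 1) if n_pos else 1
    vals = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(vals)
    coords = _orient(coords, coords)
    pos_total = eigval[eigval > tol].sum()
    fractions = vals / pos_total if pos_total > 0 else np.zeros(k)
    cdf = pd.DataFrame(
        coords, index=labels, columns=[f"Axis{i+1}" for i in range(k)]
    )
    return OrdinationResult(cdf, vals, fractions, "classical_mds")


def pca(
    freqs: pd.DataFrame, center: bool = True, scale: bool = False
) -> OrdinationResult:
    """PCA of a populations x haplogroups frequency matrix.

    Covariance mode by default (frequencies share a scale); ``scale=True``
    switches to correlation mode.  Returns scores, loadings and variance
    fractions (summing to 1 over all axes).
    """
    if freqs.shape[0] < 2 or freqs.shape[1] < 2:
        raise ValueError("PCA needs at least 2 populations and 2 variables")
    x = freqs.to_numpy(dtype=float)
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
        var_names = list(freqs.columns[keep])
    else:
        var_names = list(freqs.columns)
    if not np.any(x):
        raise ValueError("matrix has no variance; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_axes = min(x.shape[0] - 1 if center else x.shape[0], x.shape[1])
    n_axes = max(n_axes, 1)
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    scores = u * s
    loadings = vt.T
    scores = _orient(scores, loadings)
    loadings = _orient(loadings, loadings)
    explained = s ** 2 / max(x.shape[0] - 1, 1)
    fractions = explained / explained.sum()
    axes = [f"PC{i+1}" for i in range(n_axes)]
    return OrdinationResult(
        pd.DataFrame(scores, index=freqs.index, columns=axes),
        explained,
        fractions,
        "pca",
        loadings=pd.DataFrame(loadings, index=var_names, columns=axes),
    )
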