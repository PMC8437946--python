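"""Shared numerical primitives: masked Pearson cross-correlation and Ward clustering.

The cross-correlation of a gene-expression matrix against a methylation
matrix is the workhorse of the whole pipeline, so it is implemented once
here with a fast dense path and a pairwise-complete (missing-aware) path.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

_EPS = 1e-12


def pairwise_pearson(
    X: np.ndarray,
    Y: np.ndarray,
    min_n: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between columns of ``X`` and columns of ``Y``.

    Both matrices are samples x features over the *same* samples.  Missing
    values (NaN) are handled pairwise-complete: each (i, j) cell uses only
    samples observed in both profiles.  Cells supported by fewer than
    ``min_n`` samples, or involving a zero-variance profile, are NaN.

    Returns
    -------
    r : (p, q) correlation matrix
    n : (p, q) pairwise support counts
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the sample axis")
    if not (np.isnan(X).any() or np.isnan(Y).any()):
        r = _dense_pearson(X, Y)
        n = np.full(r.shape, X.shape[0], dtype=np.int64)
        if X.shape[0] < min_n:
            r[:] = np.nan
        return r, n

    mx = ~np.isnan(X)
    my = ~np.isnan(Y)
    Xz = np.where(mx, X, 0.0)
    Yz = np.where(my, Y, 0.0)
    fmx = mx.astype(np.float64)
    fmy = my.astype(np.float64)

    n = fmx.T @ fmy
    sx = Xz.T @ fmy
    sy = fmx.T @ Yz
    sxx = (Xz * Xz).T @ fmy
    syy = fmx.T @ (Yz * Yz)
    sxy = Xz.T @ Yz

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[(n < max(min_n, 2)) | (vx <= _EPS) | (vy <= _EPS)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return r, n.astype(np.int64)


def _dense_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlation between columns of complete matrices via one matmul."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sdx = np.sqrt((Xc * Xc).sum(axis=0))
    sdy = np.sqrt((Yc * Yc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Yc) / np.outer(sdx, sdy)
    r[np.ix_(sdx <= _EPS, np.arange(Y.shape[1]))] = np.nan
    r[:, sdy <= _EPS] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    if n < 2:
        r[:] = np.nan
    return r


def blockwise_self_pearson(X: np.ndarray, block: int = 2048) -> np.ndarray:
    """Correlation matrix among columns of ``X`` computed in column blocks.

    Numerically identical (to fp round-off) to a single full computation;
    the block size only bounds peak memory.
    """
    p = X.shape[1]
    Xc = X - np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(Xc), 0.0, Xc)
    sd = np.sqrt((Xc * Xc).sum(axis=0))
    out = np.empty((p, p), dtype=np.float64)
    for lo in range(0, p, block):
        hi = min(lo + block, p)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[lo:hi] = (Xc[:, lo:hi].T @ Xc) / np.outer(sd[lo:hi], sd)
    out[sd <= _EPS, :] = np.nan
    out[:, sd <= _EPS] = np.nan
    np.clip(out, -1.0, 1.0, out=out)
    return out


def ward_cluster(vectors: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward clustering of row vectors under Euclidean distance.

    Uses the Ward variant in which the pairwise Euclidean distances are
    squared inside the merge criterion (the ``ward.D2`` convention), which
    is what :func:`scipy.cluster.hierarchy.linkage` implements on raw
    observations.  Cluster ids are relabeled 1..k in dendrogram leaf order
    so that two runs on identical input give identical labels.
    """
    n = vectors.shape[0]
    if n == 0:
        raise ValueError("cannot cluster zero vectors")
    if n_clusters > n:
        warnings.warn(
            f"requested {n_clusters} clusters for {n} rows; reducing to {n}",
            stacklevel=2,
        )
        n_clusters = n
    if n == 1:
        return np.array([1])
    Z = linkage(vectors, method="ward")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    return _relabel_by_leaf_order(raw, leaves_list(Z))


def _relabel_by_leaf_order(labels: np.ndarray, leaves: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    for leaf in leaves:
        lab = labels[leaf]
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[v] for v in labels], dtype=np.int64)
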