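"""K-nearest-neighbor normalization of methylation in immune/CAF
signature space, and the raw-methylation TME scores.

Each tumor's methylation is compared against the mean of its K nearest
neighbors in the 2D (immune signature, CAF signature) plane; subtracting
that neighborhood mean removes methylation variation explained by cell
composition while preserving tumor-intrinsic signals orthogonal to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core import MethylMatrix, Parameters


@dataclass
class NormalizedMethylMatrix:
    """Residual methylation after neighborhood-mean subtraction.

    ``values`` has the same shape as the raw matrix but lives in [-1, 1];
    ``neighbors`` lists, per sample, the K neighbor sample ids used.
    """

    values: pd.DataFrame
    neighbors: pd.DataFrame  # samples x K
    k: int

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def find_neighbors(
    immune_score: pd.Series,
    caf_score: pd.Series,
    k: int,
    zscore_axes: bool = True,
) -> pd.DataFrame:
    """K nearest neighbors of each sample in the 2D signature plane.

    Axes are z-scored by default so that neither signature dominates the
    Euclidean distance.  Self is excluded; exact distance ties resolve by
    stable input order.
    """
    samples = immune_score.index
    if not caf_score.index.equals(samples):
        raise ValueError("immune and CAF scores must cover the same samples")
    n = len(samples)
    if k >= n:
        raise ValueError(f"K={k} must be smaller than the sample count {n}")
    X = np.column_stack([immune_score.to_numpy(float), caf_score.to_numpy(float)])
    if np.isnan(X).any():
        raise ValueError("signature scores must be available for every sample")
    if zscore_axes:
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = [j for j in idx[i] if j != i][:k]
        if len(row) < k:  # duplicate coordinates: self dropped twice
            extra = [j for j in range(n) if j != i and j not in row]
            row += extra[: k - len(row)]
        out[i] = row
    return pd.DataFrame(
        samples.to_numpy()[out], index=samples,
        columns=[f"nn{j + 1}" for j in range(k)],
    )


def knn_normalize(
    meth: MethylMatrix | pd.DataFrame,
    immune_score: pd.Series,
    caf_score: pd.Series,
    k: int | None = None,
    params: Parameters | None = None,
    group: str = "ER+",
) -> NormalizedMethylMatrix:
    """Subtract from each tumor's raw methylation the mean methylation of
    its K nearest neighbors in immune/CAF signature space.

    Per locus, the neighborhood mean uses non-missing neighbor values
    only; cells where fewer than K/2 neighbors are observed become
    missing.  K defaults to the group-specific setting (30 for ER+, 15
    for ER-/normal).
    """
    p = params or Parameters()
    values = meth.values if isinstance(meth, MethylMatrix) else meth
    k = k if k is not None else p.knn_k_for(group)
    samples = values.columns
    neighbors = find_neighbors(
        immune_score.loc[samples], caf_score.loc[samples], k,
        zscore_axes=p.zscore_signature_axes,
    )
    V = values.to_numpy(dtype=np.float64)
    pos = {s: i for i, s in enumerate(samples)}
    nidx = np.vectorize(pos.get)(neighbors.to_numpy())

    obs = ~np.isnan(V)
    Vz = np.where(obs, V, 0.0)
    nbr_sum = Vz[:, nidx].sum(axis=2)
    nbr_n = obs[:, nidx].sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbr_mean = nbr_sum / nbr_n
    resid = V - nbr_mean
    resid[nbr_n < k / 2] = np.nan
    return NormalizedMethylMatrix(
        values=pd.DataFrame(resid, index=values.index, columns=samples),
        neighbors=neighbors,
        k=k,
    )


def tme_methylation_score(
    raw_meth: MethylMatrix | pd.DataFrame,
    signature: pd.Series,
    params: Parameters | None = None,
) -> pd.Series:
    """Raw-methylation TME score for one signature (immune or CAF).

    Averages the raw methylation of all promoters whose profile is
    negatively correlated (< -0.3 by default) with the expression
    signature.  The score *falls* as the corresponding cell fraction
    rises, because unmethylated non-tumor DNA dilutes these promoters.
    """
    p = params or Parameters()
    values = raw_meth.values if isinstance(raw_meth, MethylMatrix) else raw_meth
    shared = values.columns.intersection(signature.index)
    vals = values[shared]
    sig = signature.loc[shared].to_numpy(float)

    from ._stats import pairwise_pearson

    r, _ = pairwise_pearson(vals.to_numpy().T, sig[:, None], min_n=3)
    qualifying = vals.index[r[:, 0] < p.tme_corr_threshold]
    if len(qualifying) == 0:
        warnings.warn("no promoter correlates below the TME threshold; score undefined")
        return pd.Series(np.nan, index=shared)
    return vals.loc[qualifying].mean(axis=0, skipna=True)


def knn_sensitivity_sweep(
    meth: MethylMatrix | pd.DataFrame,
    immune_score: pd.Series,
    caf_score: pd.Series,
    truth_fraction: pd.Series,
    tme_loci: pd.Index,
    ks: tuple[int, ...] = (5, 15, 30, 60),
    params: Parameters | None = None,
) -> pd.DataFrame:
    """Recovery metrics across a range of K values.

    For each K, reports the fraction of TME loci whose normalized profile
    decorrelates (|r| < 0.1) from the true contaminating fraction, and
    the residual noise (mean |normalized value| at TME loci).  Documents
    the noise-bias trade-off: small K = noisy neighborhood means, large
    K = less effective normalization.
    """
    from ._stats import pairwise_pearson

    values = meth.values if isinstance(meth, MethylMatrix) else meth
    rows = []
    f = truth_fraction.loc[values.columns].to_numpy(float)
    for k in ks:
        norm = knn_normalize(values, immune_score, caf_score, k=k, params=params)
        sub = norm.values.loc[tme_loci]
        r, _ = pairwise_pearson(sub.to_numpy().T, f[:, None], min_n=3)
        rows.append(
            {
                "k": k,
                "frac_decorrelated": float(np.mean(np.abs(r[:, 0]) < 0.1)),
                "mean_abs_residual": float(sub.abs().mean().mean()),
            }
        )
    return pd.DataFrame(rows).set_index("k")
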