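"""Expression x promoter-methylation cross-correlation, clustering, and
identification of immune / CAF (tumor-microenvironment) gene modules.

The cross-correlation matrix is the entry point of the deconvolution:
groups of genes whose expression tracks the methylation of many promoters
at once flag cell-composition effects rather than gene-level regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import pairwise_pearson, ward_cluster
from .core import ExprMatrix, MethylMatrix, Parameters, SampleMetadata

DEFAULT_IMMUNE_ANCHORS = ("CD3D", "CD3E", "CD8A", "CTLA4", "PDCD1")
DEFAULT_CAF_ANCHORS = ("CAV1", "FAP", "VIM")


@dataclass
class CrossCorrMatrix:
    """Genes x promoter-loci Pearson correlations with cluster labels."""

    r: pd.DataFrame  # genes x loci
    n_support: pd.DataFrame
    row_clusters: Optional[pd.Series] = None  # per gene
    col_clusters: Optional[pd.Series] = None  # per locus
    group: Optional[str] = None


@dataclass
class TMEModules:
    """Gene sets anchoring the immune and CAF expression signatures."""

    immune_genes: list[str]
    caf_genes: list[str]
    anchor_evidence: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if set(self.immune_genes) & set(self.caf_genes):
            raise ValueError("immune and CAF modules must be disjoint")


def build_cross_correlation(
    expr: ExprMatrix,
    meth: MethylMatrix,
    params: Parameters | None = None,
    metadata: SampleMetadata | None = None,
    group: str | None = None,
) -> CrossCorrMatrix:
    """Pairwise-complete Pearson correlation of expression vs promoter
    methylation over one sample group.

    Loci with mean methylation below 0.1 or above 0.9 are excluded before
    correlating; cells supported by fewer than ``min_corr_samples``
    samples are missing; genes (rows) and loci (columns) without at least
    one correlation of magnitude > ``corr_floor`` are dropped.
    """
    p = params or Parameters()
    shared = expr.samples.intersection(meth.samples)
    if group is not None:
        if metadata is None:
            raise ValueError("selecting a group requires sample metadata")
        shared = shared.intersection(metadata.samples_in_group(group))
    if len(shared) < p.min_corr_samples:
        raise ValueError(
            f"only {len(shared)} shared samples; need >= {p.min_corr_samples}"
        )
    shared = list(shared)

    mvals = meth.values[shared]
    lo, hi = p.meth_mean_bounds
    mean_meth = mvals.mean(axis=1, skipna=True)
    keep_loci = (mean_meth >= lo) & (mean_meth <= hi)
    mvals = mvals.loc[keep_loci]
    evals = expr.values[shared]

    r, n = pairwise_pearson(
        evals.to_numpy().T, mvals.to_numpy().T, min_n=p.min_corr_samples
    )
    r = pd.DataFrame(r, index=evals.index, columns=mvals.index)
    n = pd.DataFrame(n, index=evals.index, columns=mvals.index)

    strong = r.abs() > p.corr_floor
    keep_rows = strong.any(axis=1)
    keep_cols = strong.any(axis=0)
    return CrossCorrMatrix(
        r=r.loc[keep_rows, keep_cols],
        n_support=n.loc[keep_rows, keep_cols],
        group=group,
    )


def cluster_cross_correlation(
    C: CrossCorrMatrix,
    n_clusters: int | None = None,
    params: Parameters | None = None,
) -> CrossCorrMatrix:
    """Cluster rows (genes) and columns (loci) of the cross-correlation
    matrix independently with Ward linkage on Euclidean distances.

    Missing correlations are imputed as 0 (neutral under Euclidean
    distance) for clustering only.  Cluster ids follow dendrogram leaf
    order, so two runs on identical input give identical labels.
    """
    p = params or Parameters()
    k = n_clusters if n_clusters is not None else p.n_cross_clusters
    filled = C.r.fillna(0.0)
    row_labels = ward_cluster(filled.to_numpy(), k)
    col_labels = ward_cluster(filled.to_numpy().T, k)
    C.row_clusters = pd.Series(row_labels, index=C.r.index, name="cluster")
    C.col_clusters = pd.Series(col_labels, index=C.r.columns, name="cluster")
    return C


def identify_tme_modules(
    C: CrossCorrMatrix,
    immune_anchors: Sequence[str] = DEFAULT_IMMUNE_ANCHORS,
    caf_anchors: Sequence[str] = DEFAULT_CAF_ANCHORS,
    immune_cluster: int | None = None,
    caf_cluster: int | None = None,
) -> TMEModules:
    """Locate the gene clusters carrying the immune and CAF signatures.

    For each anchor set (canonical T-cell / fibroblast markers by
    default), the gene cluster containing the plurality of anchors is
    returned.  Ambiguity (tied plurality, anchors absent, or both sets in
    one cluster) raises and asks for a manual cluster override.
    """
    if C.row_clusters is None:
        raise ValueError("cross-correlation matrix must be clustered first")

    def _pick(anchors: Sequence[str], override: int | None, name: str) -> int:
        if override is not None:
            return override
        present = [a for a in anchors if a in C.row_clusters.index]
        if not present:
            raise ValueError(f"no {name} anchor genes found in the matrix: {anchors}")
        counts = C.row_clusters.loc[present].value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            raise ValueError(
                f"{name} anchors split without plurality "
                f"({dict(counts)}); pass {name}_cluster= explicitly"
            )
        return int(counts.index[0])

    imm = _pick(immune_anchors, immune_cluster, "immune")
    caf = _pick(caf_anchors, caf_cluster, "caf")
    if imm == caf:
        raise ValueError(
            f"immune and CAF anchors landed in the same cluster ({imm}); "
            "pass explicit cluster overrides"
        )
    evidence = pd.DataFrame(
        {
            "anchor": list(immune_anchors) + list(caf_anchors),
            "set": ["immune"] * len(immune_anchors) + ["caf"] * len(caf_anchors),
            "cluster": [
                C.row_clusters.get(a, np.nan)
                for a in list(immune_anchors) + list(caf_anchors)
            ],
        }
    )
    return TMEModules(
        immune_genes=list(C.row_clusters.index[C.row_clusters == imm]),
        caf_genes=list(C.row_clusters.index[C.row_clusters == caf]),
        anchor_evidence=evidence,
    )


def compute_signature(expr: ExprMatrix, gene_set: Sequence[str]) -> pd.Series:
    """Per-sample signature: mean log expression over a gene set."""
    present = [g for g in gene_set if g in expr.values.index]
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    return expr.values.loc[present].mean(axis=0)
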