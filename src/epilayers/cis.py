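"""Rank-based screening for in-cis expression-methylation regulation.

Promoter screen: a gene's own promoter should correlate with the gene's
expression more strongly than essentially any of the thousands of other
promoters - otherwise the correlation is plausibly a global trans trend.
Ranks of the own-promoter ("diagonal") correlation across all promoters
give an empirical FDR: at rank threshold k, FDR = k / m where m is the
number of genes whose diagonal rank is <= k.

Distal screen: each non-promoter locus is paired with its best-correlated
gene; pairing is called when that gene's TSS lies within 500 kb on the
same chromosome, and the pairing FDR is the ratio of pairing counts in
sample-shuffled versus real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pairwise_pearson
from .core import Parameters


@dataclass
class CisScreenResult:
    """Promoter screen output: per-gene diagonal rank and the FDR curve."""

    table: pd.DataFrame  # gene, r_cis, rank, n_support, fdr_at_rank
    fdr_curve: pd.DataFrame  # k, m, fdr
    direction: str  # "negative" or "positive"

    def genes_at_fdr(self, alpha: float) -> list[str]:
        """Genes whose diagonal rank is within the largest k with FDR <= alpha."""
        ok = self.fdr_curve[self.fdr_curve["fdr"] <= alpha]
        if ok.empty:
            return []
        k_star = int(ok["k"].max())
        t = self.table
        return list(t.loc[t["rank"] <= k_star, "gene"])

    def genes_at_rank(self, k: int = 1) -> list[str]:
        t = self.table
        return list(t.loc[t["rank"] <= k, "gene"])


def promoter_cis_screen(
    expr: pd.DataFrame,
    meth: pd.DataFrame,
    params: Parameters | None = None,
    exclude_genes: Sequence[str] = (),
    direction: str = "negative",
) -> CisScreenResult:
    """Screen promoters for in-cis correlation with their own gene.

    ``expr`` and ``meth`` are square-matched: row i of ``meth`` is the
    resolved promoter of the gene in row i of ``expr`` (identical index),
    columns are shared samples.  Genes in ``exclude_genes`` (e.g. the
    immune/CAF modules) are removed before ranking.

    ``direction="negative"`` ranks correlations ascending (rank 1 = the
    strongest negative, methylation-repression); ``"positive"`` is the
    mirrored pass for methylation-associated induction.
    """
    p = params or Parameters()
    if not expr.index.equals(meth.index):
        raise ValueError("expression and methylation must be square-matched by gene")
    if exclude_genes:
        keep = ~expr.index.isin(set(exclude_genes))
        expr, meth = expr.loc[keep], meth.loc[keep]
    shared = expr.columns.intersection(meth.columns)
    E = expr[shared].to_numpy().T
    M = meth[shared].to_numpy().T

    r, n = pairwise_pearson(M, E, min_n=p.min_corr_samples)  # promoters x genes
    diag = np.diag(r)
    if np.all(np.isnan(diag)):
        raise ValueError("no gene has an observed own-promoter correlation")

    sign = 1.0 if direction == "negative" else -1.0
    if direction not in ("negative", "positive"):
        raise ValueError("direction must be 'negative' or 'positive'")

    genes = expr.index.to_numpy()
    n_genes = len(genes)
    ranks = np.full(n_genes, np.nan)
    for j in range(n_genes):
        col = sign * r[:, j]
        if np.isnan(col[j]):
            continue
        order = np.lexsort((np.arange(n_genes), col))  # ties -> promoter order
        valid = ~np.isnan(col[order])
        pos = np.empty(n_genes, dtype=np.int64)
        pos[order[valid]] = np.arange(1, valid.sum() + 1)
        ranks[j] = pos[j]

    observed = ~np.isnan(ranks)
    table = pd.DataFrame(
        {
            "gene": genes[observed],
            "r_cis": diag[observed],
            "rank": ranks[observed].astype(np.int64),
            "n_support": np.diag(n)[observed],
        }
    )

    ks = np.arange(1, n_genes + 1)
    diag_ranks = np.sort(table["rank"].to_numpy())
    m = np.searchsorted(diag_ranks, ks, side="right")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(m > 0, ks / np.maximum(m, 1), np.inf)
    fdr_curve = pd.DataFrame({"k": ks, "m": m, "fdr": fdr})
    table["fdr_at_rank"] = [
        float(fdr_curve.loc[fdr_curve["k"] == k, "fdr"].iloc[0]) for k in table["rank"]
    ]
    return CisScreenResult(table=table, fdr_curve=fdr_curve, direction=direction)


@dataclass
class DistalScreenResult:
    """Distal pairing output with its shuffled-control FDR estimate."""

    table: pd.DataFrame  # locus, best_gene, r_best, distance, paired
    n_paired: int
    shuffled_paired: list[int]
    fdr: float
    distance_report: pd.DataFrame = field(default_factory=pd.DataFrame)


def distal_cis_screen(
    expr: pd.DataFrame,
    gene_coords: pd.DataFrame,
    meth: pd.DataFrame,
    locus_coords: pd.DataFrame,
    params: Parameters | None = None,
    n_shuffles: int = 10,
    seed: int = 0,
) -> DistalScreenResult:
    """Pair non-promoter loci with their best-correlated gene.

    For every locus the gene with the maximum |r| is selected (ties break
    by gene id); the locus is "paired" when that gene's TSS is on the
    same chromosome within ``distal_window`` (500 kb) of the locus
    midpoint.  The expected chance pairing rate comes from re-running the
    same selection after permuting the sample labels of the expression
    matrix (``n_shuffles`` times, seeded); FDR = mean shuffled pairing
    count / real pairing count.
    """
    p = params or Parameters()
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    shared = list(expr.columns.intersection(meth.columns))
    E = expr[shared].to_numpy().T
    M = meth[shared].to_numpy().T

    mid = ((locus_coords["start"] + locus_coords["end"]) // 2).to_numpy()
    locus_chrom = locus_coords["chrom"].to_numpy()
    tss = gene_coords["tss"].to_numpy()
    gene_chrom = gene_coords["chrom"].to_numpy()

    def _pair_counts(Emat: np.ndarray):
        r, _ = pairwise_pearson(M, Emat, min_n=p.min_corr_samples)
        a = np.abs(r)
        a = np.where(np.isnan(a), -1.0, a)
        best = np.argmax(a, axis=1)  # ties: first (gene order) wins
        best_r = r[np.arange(len(best)), best]
        same = gene_chrom[best] == locus_chrom
        dist = np.abs(mid - tss[best])
        paired = same & (dist <= p.distal_window)
        return best, best_r, dist, paired

    best, best_r, dist, paired = _pair_counts(E)
    shuffled_counts = []
    for _ in range(n_shuffles):
        perm = rng.permutation(E.shape[0])
        shuffled_counts.append(int(_pair_counts(E[perm])[3].sum()))

    n_paired = int(paired.sum())
    fdr = float(np.mean(shuffled_counts) / n_paired) if n_paired else np.inf
    table = pd.DataFrame(
        {
            "locus": locus_coords.index,
            "best_gene": gene_coords.index.to_numpy()[best],
            "r_best": best_r,
            "distance": np.where(
                gene_chrom[best] == locus_chrom, dist, np.nan
            ),
            "paired": paired,
        }
    )
    d = table.loc[table["paired"], "distance"]
    distance_report = pd.DataFrame(
        {
            "n_paired": [n_paired],
            "frac_within_50kb": [float((d <= 50_000).mean()) if n_paired else np.nan],
            "frac_50_500kb": [
                float(((d > 50_000) & (d <= 500_000)).mean()) if n_paired else np.nan
            ],
        }
    )
    return DistalScreenResult(
        table=table,
        n_paired=n_paired,
        shuffled_paired=shuffled_counts,
        fdr=min(fdr, np.inf),
        distance_report=distance_report,
    )


def epiconvergence_report(
    cis_epipoly: pd.Series,
    cis_avg_meth: pd.Series,
    background_epipoly: pd.Series,
    background_avg_meth: pd.Series,
    strata: Sequence[float] = (0.0, 0.1, 0.3, 0.7, 1.0),
    correction: str = "holm",
) -> pd.DataFrame:
    """Compare epiallele diversity of cis candidates versus background
    within average-methylation strata.

    One-sided Mann-Whitney per stratum, alternative: cis loci are *less*
    epi-polymorphic (convergent epialleles).  Empty strata are skipped.
    """
    from statsmodels.stats.multitest import multipletests

    edges = list(strata)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        cis_ids = cis_avg_meth.index[(cis_avg_meth >= lo) & (cis_avg_meth < hi)]
        bg_ids = background_avg_meth.index[
            (background_avg_meth >= lo) & (background_avg_meth < hi)
        ]
        x = cis_epipoly.loc[cis_ids].dropna()
        y = background_epipoly.loc[bg_ids].dropna()
        if len(x) == 0 or len(y) == 0:
            continue
        if x.nunique() == 1 and y.nunique() == 1 and x.iloc[0] == y.iloc[0]:
            pval = 1.0
        else:
            pval = float(stats.mannwhitneyu(x, y, alternative="less").pvalue)
        rows.append(
            {
                "stratum_lo": lo, "stratum_hi": hi,
                "n_cis": len(x), "n_background": len(y),
                "median_cis": float(x.median()), "median_background": float(y.median()),
                "p": pval,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method=correction)[1]
    return out
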