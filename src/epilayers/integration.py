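"""Integration of methylation scores with genomic features: mutation and
copy-number associations, chromosomal-instability stratification, MATH
intra-tumor heterogeneity, and copy-number dosage compensation through
methylation (the X-chromosome pattern generalized to autosomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Parameters


def associate_scores(
    scores: pd.DataFrame,
    features: pd.DataFrame,
    params: Parameters | None = None,
) -> pd.DataFrame:
    """Associate each per-sample score with each genomic feature.

    Binary features (mutation present/absent, CNA gained/not) are tested
    with a two-sided Wilcoxon rank-sum comparing score distributions;
    continuous features (CIN, MATH) with Spearman correlation.  A
    sample-count-balanced 5-quantile stratification of each score is
    reported as mutation frequency per stratum.  P-values are
    Benjamini-Hochberg corrected over all feature x score pairs;
    degenerate features are skipped.
    """
    p = params or Parameters()
    shared = scores.index.intersection(features.index)
    rows = []
    for feat in features.columns:
        fvals = features.loc[shared, feat]
        observed = fvals.dropna()
        uniq = observed.unique()
        if len(uniq) < 2:
            continue
        binary = set(np.unique(observed)) <= {0, 1, False, True}
        for score in scores.columns:
            s = scores.loc[shared, score]
            ok = s.notna() & fvals.notna()
            s, f = s[ok], fvals[ok]
            if binary:
                a, b = s[f.astype(bool)], s[~f.astype(bool)]
                if len(a) < p.min_group_size or len(b) < p.min_group_size:
                    continue
                stat, pval = stats.ranksums(a, b)
                effect = float(a.median() - b.median())
                strata = pd.qcut(s, p.n_mut_strata, labels=False, duplicates="drop")
                freq = {
                    f"freq_q{int(q) + 1}": float(f[strata == q].mean())
                    for q in sorted(strata.dropna().unique())
                }
            else:
                if len(s) < 2 * p.min_group_size:
                    continue
                stat, pval = stats.spearmanr(s, f)
                effect = float(stat)
                freq = {}
            rows.append({
                "feature": feat, "score": score,
                "kind": "binary" if binary else "continuous",
                "statistic": float(stat), "p": float(pval), "effect": effect,
                **freq,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class DosageResult:
    """Per-gene copy-number contrast table and the compensated calls."""

    table: pd.DataFrame

    def compensated_genes(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["compensated"], "gene"].unique())


def dosage_compensation(
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    cn_states: pd.DataFrame,
    params: Parameters | None = None,
    contrasts: tuple[tuple[int, int], ...] = ((1, 2), (3, 2), (4, 2)),
) -> DosageResult:
    """Screen genes for methylation-mediated dosage compensation.

    For each gene and copy-number contrast (1N vs 2N, 3N vs 2N, 4N vs 2N),
    promoter methylation and expression are compared between the strata
    with two-sample Kolmogorov-Smirnov tests.  A gene is *compensated*
    when methylation shifts in the compensating direction (up on gain,
    down on loss) at BH q < 0.05 while expression shows no significant
    scaling with copy number (p >= 0.05).  Contrasts with a stratum below
    ``min_cn_stratum`` samples are skipped.
    """
    p = params or Parameters()
    genes = meth.index.intersection(expr.index).intersection(cn_states.index)
    shared = meth.columns.intersection(expr.columns).intersection(cn_states.columns)
    rows = []
    for g in genes:
        cn = cn_states.loc[g, shared]
        m = meth.loc[g, shared]
        e = expr.loc[g, shared]
        for alt, ref in contrasts:
            a = cn == alt
            b = cn == ref
            if a.sum() < p.min_cn_stratum or b.sum() < p.min_cn_stratum:
                continue
            meth_ks = stats.ks_2samp(m[a], m[b])
            expr_ks = stats.ks_2samp(e[a], e[b])
            shift = float(m[a].mean() - m[b].mean())
            compensating = shift > 0 if alt > ref else shift < 0
            rows.append({
                "gene": g, "contrast": f"{alt}N_vs_{ref}N",
                "n_alt": int(a.sum()), "n_ref": int(b.sum()),
                "meth_shift": shift, "meth_p": float(meth_ks.pvalue),
                "expr_shift": float(e[a].mean() - e[b].mean()),
                "expr_p": float(expr_ks.pvalue),
                "compensating_direction": bool(compensating),
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["meth_q"] = multipletests(table["meth_p"], method="fdr_bh")[1]
        table["expression_scales"] = table["expr_p"] < 0.05
        table["compensated"] = (
            table["compensating_direction"]
            & (table["meth_q"] < 0.05)
            & ~table["expression_scales"]
        )
    return DosageResult(table)


def math_score(vafs) -> float:
    """Mutant-allele tumor heterogeneity: 100 * MAD(VAF) / median(VAF).

    MAD uses the 1.4826 normal-consistency constant.  Requires at least
    two variant-allele frequencies in (0, 1]; otherwise NaN.
    """
    v = np.asarray(pd.Series(vafs).dropna(), dtype=float)
    v = v[(v > 0) & (v <= 1)]
    if len(v) < 2:
        return np.nan
    mad = stats.median_abs_deviation(v, scale=1.0) * 1.4826
    return float(100.0 * mad / np.median(v))
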