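"""Inference of the global methylation layers: the replication-linked
loss clock and the two epigenomic-instability layers (MG = gain at
normally unmethylated loci, ML = loss at partially methylated loci).

Layers are found by clustering the locus-locus correlation matrix of
TME-normalized methylation into three groups, then labeled automatically
from raw methylation in normal samples (clock loci are hypermethylated in
normals, MG loci near zero, ML loci partially methylated) with a
replication-timing check on the clock.  Scores are oriented so that a
higher score always means a larger departure from the normal state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import blockwise_self_pearson, pairwise_pearson, ward_cluster
from .core import MethylMatrix, Parameters
from .knn_norm import NormalizedMethylMatrix

LAYERS = ("clock", "mg", "ml")
#: score orientation: loss layers flip sign so higher score = more aberration
ORIENTATION = {"clock": -1.0, "mg": 1.0, "ml": -1.0}


@dataclass
class LayerModel:
    """Fitted layer structure: locus assignments, correlations, scores."""

    locus_layer: pd.Series  # sampled loci -> layer name
    locus_corr: pd.Series  # correlation of each locus with its layer score
    scores: pd.DataFrame  # samples x {clock, mg, ml}, oriented
    cluster_of_layer: dict = field(default_factory=dict)
    normal_means: dict = field(default_factory=dict)

    def layer_loci(self, layer: str, min_corr: float | None = None) -> pd.Index:
        ids = self.locus_layer.index[self.locus_layer == layer]
        if min_corr is not None:
            ids = ids[self.locus_corr.loc[ids] > min_corr]
        return ids


def fit_layers(
    norm_meth: NormalizedMethylMatrix,
    raw_normals: Optional[pd.DataFrame] = None,
    tor_bin: Optional[pd.Series] = None,
    params: Parameters | None = None,
    seed: int = 0,
    loci: Optional[pd.Index] = None,
    block: int = 2048,
) -> LayerModel:
    """Cluster normalized methylation signatures into the three layers.

    Procedure: take a seeded uniform sample of up to ``layer_sample_size``
    eligible loci (default eligibility: |mean normalized methylation| <
    0.1), correlate every sampled locus against every other, drop loci
    without at least one partner at |r| > 0.25, Ward-cluster the
    correlation vectors into three groups, label the groups from normal
    raw methylation, and score each sample by the oriented mean
    normalized methylation over each layer's loci.

    Parameters
    ----------
    raw_normals : raw methylation of normal samples (loci x normals) used
        for layer labeling; absent -> a normal-free heuristic with warning.
    tor_bin : optional per-locus "late"/"early" labels used to sanity-check
        the clock label.
    loci : optional explicit locus subset (overrides sampling).
    """
    p = params or Parameters()
    rng = np.random.default_rng(seed)
    V = norm_meth.values

    if loci is None:
        mean_abs = V.mean(axis=1, skipna=True).abs()
        if p.layer_filter_on_normalized:
            eligible = V.index[mean_abs < p.layer_mean_bound]
        else:
            eligible = V.index  # raw-mean variant is applied upstream
        if len(eligible) > p.layer_sample_size:
            take = rng.choice(len(eligible), p.layer_sample_size, replace=False)
            eligible = eligible[np.sort(take)]
    else:
        eligible = pd.Index(loci)

    X = V.loc[eligible].to_numpy(dtype=np.float64).T  # samples x loci
    corr = blockwise_self_pearson(X, block=block)
    np.fill_diagonal(corr, 0.0)
    has_partner = np.nanmax(np.abs(corr), axis=1) > p.corr_floor
    kept = eligible[has_partner]
    if len(kept) < p.n_layer_clusters:
        raise ValueError(
            f"only {len(kept)} loci pass the correlation filter; "
            f"cannot form {p.n_layer_clusters} layers"
        )
    corr = corr[np.ix_(has_partner, has_partner)]
    corr = np.where(np.isnan(corr), 0.0, corr)

    labels = ward_cluster(corr, p.n_layer_clusters)
    layer_names = _label_clusters(
        kept, labels, raw_normals, norm_meth, tor_bin, p
    )

    locus_layer = pd.Series(
        [layer_names[l] for l in labels], index=kept, name="layer"
    )
    scores = {}
    normal_means = {}
    for layer in LAYERS:
        ids = locus_layer.index[locus_layer == layer]
        if len(ids) == 0:
            scores[layer] = pd.Series(np.nan, index=V.columns)
            continue
        scores[layer] = ORIENTATION[layer] * V.loc[ids].mean(axis=0, skipna=True)
        if raw_normals is not None:
            normal_means[layer] = float(
                raw_normals.loc[ids.intersection(raw_normals.index)]
                .mean(axis=1).mean()
            )
    score_df = pd.DataFrame(scores)

    corr_to_score, _ = pairwise_pearson(
        V.loc[kept].to_numpy().T, score_df.to_numpy(), min_n=3
    )
    layer_pos = {l: i for i, l in enumerate(score_df.columns)}
    locus_corr = pd.Series(
        [corr_to_score[i, layer_pos[locus_layer.iloc[i]]] for i in range(len(kept))],
        index=kept,
        name="layer_corr",
    )
    return LayerModel(
        locus_layer=locus_layer,
        locus_corr=locus_corr,
        scores=score_df,
        cluster_of_layer={v: k for k, v in layer_names.items()},
        normal_means=normal_means,
    )


def _label_clusters(
    locus_ids: pd.Index,
    labels: np.ndarray,
    raw_normals: Optional[pd.DataFrame],
    norm_meth: NormalizedMethylMatrix,
    tor_bin: Optional[pd.Series],
    p: Parameters,
) -> dict[int, str]:
    """Map cluster ids to layer names via normal-sample methylation.

    MG = lowest normal methylation (gains start from ~0); clock = highest
    (loss from hypermethylated, late-replicating loci); ML = the
    remaining, partially methylated group.  Without normals, tumor raw
    levels are unavailable here, so clusters are ranked by the mean of
    the *normalized* signal's anti-correlation structure - a weaker
    heuristic, hence the warning.
    """
    uniq = sorted(set(labels))
    if raw_normals is not None:
        shared = locus_ids.intersection(raw_normals.index)
        means = {}
        for c in uniq:
            ids = locus_ids[labels == c].intersection(shared)
            means[c] = (
                float(raw_normals.loc[ids].mean(axis=1).mean()) if len(ids) else np.nan
            )
        order = sorted(uniq, key=lambda c: (np.isnan(means[c]), means[c]))
    else:
        warnings.warn(
            "no normal samples given; labeling layers by normalized-signal "
            "heuristic", stacklevel=2,
        )
        V = norm_meth.values.loc[locus_ids]
        means = {
            c: float(V.loc[locus_ids[labels == c]].mean(axis=0).skew())
            for c in uniq
        }
        # gain layers skew positive, loss layers negative; most negative ~ clock
        order = sorted(uniq, key=lambda c: means[c])
        order = [order[0], order[-1], order[1]] if len(order) == 3 else order
        mapping = {}
        for c, name in zip(order, ["clock", "mg", "ml"][: len(order)]):
            mapping[c] = name
        return mapping

    # order by normal methylation: low -> MG, middle -> ML, high -> clock
    names_by_rank = ["mg", "ml", "clock"]
    mapping = {c: names_by_rank[min(i, 2)] for i, c in enumerate(order)}

    if tor_bin is not None:
        clock_cluster = next(c for c, n in mapping.items() if n == "clock")
        ids = locus_ids[labels == clock_cluster]
        sub = tor_bin.reindex(ids).dropna()
        bg = tor_bin.reindex(locus_ids).dropna()
        if len(sub) and len(bg):
            if (sub == "late").mean() <= (bg == "late").mean():
                warnings.warn(
                    "clock-labeled cluster is not enriched for late "
                    "replication; labeling may be unreliable", stacklevel=2,
                )
    return mapping


def project_scores(
    model: LayerModel,
    norm_meth: NormalizedMethylMatrix | pd.DataFrame,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Project the fitted layer scores onto another sample group.

    Scores are the oriented mean normalized methylation over the layer's
    loci that are present in the new matrix; a layer covered below
    ``min_coverage`` of its loci yields missing scores.
    """
    V = norm_meth.values if isinstance(norm_meth, NormalizedMethylMatrix) else norm_meth
    out = {}
    for layer in LAYERS:
        ids = model.layer_loci(layer)
        if len(ids) == 0:
            out[layer] = pd.Series(np.nan, index=V.columns)
            continue
        present = ids.intersection(V.index)
        if len(present) < min_coverage * len(ids):
            out[layer] = pd.Series(np.nan, index=V.columns)
            continue
        out[layer] = ORIENTATION[layer] * V.loc[present].mean(axis=0, skipna=True)
    return pd.DataFrame(out)


def annotate_layers(
    model: LayerModel,
    loci_meta: pd.DataFrame,
    norm_meth: NormalizedMethylMatrix | pd.DataFrame | None = None,
    normal_meth: pd.DataFrame | None = None,
    params: Parameters | None = None,
) -> dict:
    """Annotate layers against TOR, CpG content, TSS distance, enhancers.

    Returns a dict of report tables; sections whose annotation columns
    are absent are skipped.  Each continuous annotation is compared
    between layer loci and the background with a two-sample KS test.
    """
    p = params or Parameters()
    report: dict[str, pd.DataFrame] = {}

    for col, key in (("tor_value", "tor"), ("cpg_content", "cpg_content"),
                     ("tss_distance", "tss_distance")):
        if col not in loci_meta.columns:
            continue
        rows = []
        bg = loci_meta[col].reindex(loci_meta.index).dropna()
        for layer in LAYERS:
            ids = model.layer_loci(layer).intersection(loci_meta.index)
            vals = loci_meta.loc[ids, col].dropna()
            if len(vals) == 0:
                continue
            ks = stats.ks_2samp(vals, bg)
            rows.append({
                "layer": layer, "n": len(vals),
                "mean": float(vals.mean()), "background_mean": float(bg.mean()),
                "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            })
        report[key] = pd.DataFrame(rows)

    if "tor_bin" in loci_meta.columns:
        rows = []
        bins = loci_meta["tor_bin"].dropna()
        for layer in LAYERS:
            ids = model.layer_loci(layer).intersection(bins.index)
            if len(ids) == 0:
                continue
            comp = bins.loc[ids].value_counts(normalize=True)
            row = {"layer": layer, "n": len(ids)}
            for b in ("late", "intermediate", "early"):
                row[f"frac_{b}"] = float(comp.get(b, 0.0))
                row[f"background_frac_{b}"] = float((bins == b).mean())
            rows.append(row)
        report["tor_bins"] = pd.DataFrame(rows)

    if norm_meth is not None and "locus_class" in loci_meta.columns:
        V = norm_meth.values if isinstance(norm_meth, NormalizedMethylMatrix) else norm_meth
        enh = loci_meta.index[loci_meta["locus_class"] == "enhancer"]
        enh = enh.intersection(V.index)
        if len(enh):
            r, _ = pairwise_pearson(
                V.loc[enh].to_numpy().T, model.scores.to_numpy(), min_n=3
            )
            linked = pd.DataFrame(
                r, index=enh, columns=model.scores.columns
            ) > p.enhancer_link_threshold
            if normal_meth is not None:
                nm = normal_meth.reindex(enh).mean(axis=1)
                strata = pd.cut(nm, [0, 0.2, 0.6, 1.0], labels=["low", "mid", "high"],
                                include_lowest=True)
            else:
                strata = pd.Series("all", index=enh)
            rows = []
            for stratum in strata.dropna().unique():
                ids = strata.index[strata == stratum]
                for layer in model.scores.columns:
                    rows.append({
                        "normal_meth_bin": str(stratum), "layer": layer,
                        "n_enhancers": len(ids),
                        "frac_linked": float(linked.loc[ids, layer].mean()),
                    })
            report["enhancer_linkage"] = pd.DataFrame(rows)
    return report
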