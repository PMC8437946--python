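"""Genomic annotation: promoter windows, CpG aggregation, enhancer calling,
and time-of-replication binning.

Promoters are fixed windows around RefSeq-style TSSs (500 bp upstream,
50 bp downstream by default); non-promoter methylation is averaged over
MspI restriction fragments; enhancers are the top tail of an H3K4me1
coverage distribution away from promoters.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .core import Locus, Parameters


def make_promoter_window(
    chrom: str,
    tss: int,
    strand: str,
    params: Parameters | None = None,
) -> Locus:
    """Promoter window around a TSS: ``upstream`` bp before and
    ``downstream`` bp after it, strand-aware, clipped at position 0.

    On the + strand the window is [tss-500, tss+50); on the - strand the
    mirror image [tss-50, tss+500).
    """
    p = params or Parameters()
    if strand == "+":
        start, end = tss - p.promoter_upstream, tss + p.promoter_downstream
    elif strand == "-":
        start, end = tss - p.promoter_downstream, tss + p.promoter_upstream
    else:
        raise ValueError(f"promoter window requires a known strand, got {strand!r}")
    return Locus(chrom, max(0, start), end, strand=strand, locus_class="promoter")


def resolve_promoter(
    candidates: Sequence[str],
    normal_methylation: pd.DataFrame,
    coords: pd.DataFrame,
) -> Optional[str]:
    """Pick one promoter per gene among alternative candidates.

    Chooses the candidate with the minimal mean methylation across normal
    samples; ties break to the 5'-most genomic coordinate (chrom, start,
    end lexicographic) so the choice is deterministic.  Returns None when
    no candidate has any normal-sample coverage (gene flagged unresolved).

    Parameters
    ----------
    candidates : locus ids of the gene's alternative promoters
    normal_methylation : loci x normal-samples methylation values
    coords : locus metadata with chrom/start/end, indexed by locus id
    """
    if len(candidates) == 0:
        raise ValueError("at least one candidate promoter is required")
    means = normal_methylation.loc[list(candidates)].mean(axis=1, skipna=True)
    means = means.dropna()
    if means.empty:
        return None
    best = means.min()
    tied = means.index[np.isclose(means.to_numpy(), best)]
    if len(tied) == 1:
        return tied[0]
    order = coords.loc[tied, ["chrom", "start", "end"]].sort_values(
        ["chrom", "start", "end"]
    )
    return order.index[0]


def aggregate_methylation(
    meth_calls: Sequence[int],
    total_calls: Sequence[int],
    weighted: bool = True,
) -> float:
    """Aggregate per-CpG calls within one locus to a methylation fraction.

    Default is the read-pooled ratio sum(meth) / sum(total), i.e. CpGs are
    weighted by their coverage; ``weighted=False`` averages per-CpG
    fractions instead.  Zero covered CpGs yield NaN (missing).
    """
    meth = np.asarray(meth_calls, dtype=np.float64)
    tot = np.asarray(total_calls, dtype=np.float64)
    if meth.shape != tot.shape:
        raise ValueError("methylated and total call vectors must align")
    if np.any(meth > tot) or np.any(meth < 0):
        raise ValueError("methylated calls must lie in [0, total]")
    covered = tot > 0
    if not covered.any():
        return np.nan
    if weighted:
        return float(meth[covered].sum() / tot[covered].sum())
    return float(np.mean(meth[covered] / tot[covered]))


def _to_pyranges(df: pd.DataFrame) -> pr.PyRanges:
    return pr.PyRanges(
        df.rename(columns={"chrom": "Chromosome", "start": "Start", "end": "End"})[
            ["Chromosome", "Start", "End"]
        ].assign(_idx=np.arange(len(df)))
    )


def interval_distance(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Distance in bp from each query interval to the nearest subject
    interval (0 when overlapping; inf when the chromosome has no subject).
    """
    if len(subject) == 0:
        return np.full(len(query), np.inf)
    q = _to_pyranges(query)
    s = _to_pyranges(subject)
    near = q.nearest(s).df
    out = np.full(len(query), np.inf)
    if len(near):
        # pyranges Distance = gap + 1 for disjoint intervals, 0 for overlap
        d = near["Distance"].to_numpy(dtype=np.float64)
        d = np.where(d > 0, d - 1, 0.0)
        out[near["_idx"].to_numpy()] = d
    return out


def exclude_overlapping_fragments(
    fragments: pd.DataFrame,
    promoters: pd.DataFrame,
    exons: Optional[pd.DataFrame] = None,
) -> pd.Index:
    """Fragment ids that overlap no promoter window and no exon.

    Restriction fragments with any overlap to a promoter window (or an
    exon, when an exon annotation is supplied) are dropped from the
    non-promoter methylation set.
    """
    keep = np.ones(len(fragments), dtype=bool)
    for other in (promoters, exons):
        if other is None or len(other) == 0:
            continue
        hits = _to_pyranges(fragments).overlap(_to_pyranges(other)).df
        if len(hits):
            keep[hits["_idx"].to_numpy()] = False
    return fragments.index[keep]


def call_enhancers(
    coverage: pd.DataFrame,
    promoter_windows: pd.DataFrame,
    params: Parameters | None = None,
) -> list[Locus]:
    """Call putative enhancers from an H3K4me1 coverage track.

    Keeps intervals in the top tail of the coverage distribution (default
    top 3%, ties at the threshold retained), removes intervals within
    2 kb of any promoter window, and homogenizes survivors to 200 bp by
    centering on the interval midpoint.

    Parameters
    ----------
    coverage : bedGraph-like frame with chrom/start/end/value columns
    promoter_windows : frame with chrom/start/end columns
    """
    p = params or Parameters()
    if len(coverage) == 0:
        return []
    vals = coverage["value"].to_numpy(dtype=np.float64)
    thresh = np.quantile(vals, 1.0 - p.enhancer_top_quantile)
    top = coverage.loc[vals >= thresh].reset_index(drop=True)
    if len(promoter_windows):
        dist = interval_distance(top, promoter_windows)
        top = top.loc[dist > p.enhancer_promoter_exclusion]
    half = p.enhancer_width // 2
    out = []
    for row in top.itertuples(index=False):
        mid = (row.start + row.end) // 2
        start = max(0, mid - half)
        out.append(Locus(row.chrom, start, start + p.enhancer_width, locus_class="enhancer"))
    return out


def bin_time_of_replication(
    tor_values: pd.Series,
    scheme: str = "two",
    params: Parameters | None = None,
) -> pd.Series:
    """Bin replication-timing values per locus.

    ``scheme="two"``: median split; values <= median are "late" (ties at
    the median go to "late"), values above are "early".
    ``scheme="three"``: bottom 20% "late", 20-60% "intermediate",
    >60% "early" (quantile boundaries configurable).

    All-missing input yields an all-NaN labeling (downstream TOR analyses
    are skipped).
    """
    p = params or Parameters()
    vals = tor_values.astype(np.float64)
    out = pd.Series(pd.NA, index=vals.index, dtype="object")
    ok = vals.notna()
    if not ok.any():
        return out
    v = vals[ok].to_numpy()
    if scheme == "two":
        med = np.median(v)
        out[ok] = np.where(v <= med, "late", "early")
    elif scheme == "three":
        lo = np.quantile(v, p.tor_late_quantile)
        hi = np.quantile(v, p.tor_early_quantile)
        lab = np.where(v <= lo, "late", np.where(v <= hi, "intermediate", "early"))
        out[ok] = lab
    else:
        raise ValueError(f"unknown TOR binning scheme {scheme!r}")
    return out


def tss_distance(loci: pd.DataFrame, tss_table: pd.DataFrame) -> pd.Series:
    """Distance from each locus midpoint to the nearest TSS on the same
    chromosome (inf when no TSS shares the chromosome)."""
    mids = ((loci["start"] + loci["end"]) // 2).to_numpy()
    query = pd.DataFrame(
        {"chrom": loci["chrom"].to_numpy(), "start": mids, "end": mids + 1}
    )
    subject = pd.DataFrame(
        {
            "chrom": tss_table["chrom"].to_numpy(),
            "start": tss_table["tss"].to_numpy(),
            "end": tss_table["tss"].to_numpy() + 1,
        }
    )
    return pd.Series(interval_distance(query, subject), index=loci.index)
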