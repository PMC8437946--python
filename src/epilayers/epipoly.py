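"""Read-level epiallele homogenization and epi-polymorphism.

Reads mapped to one MspI restriction fragment are projected onto the
fragment's five most-covered CpGs, giving 5-bit epialleles (32 possible
patterns).  After downsampling to a fixed depth of 30 reads per fragment
and tumor, epi-polymorphism is the Gini-Simpson diversity 1 - sum(p_i^2)
of the epiallele frequencies: 0 for a homogeneous locus, at most 1 - 1/30
when all 30 reads differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import Parameters


@dataclass
class PatternSet:
    """Homogenized epiallele counts for one fragment (and sample)."""

    fragment_id: str
    positions: list[int]  # the selected CpG positions, ascending
    counts: dict[str, int]  # pattern string ("01011") -> read count
    downsampled: bool = False
    uncovered: bool = False
    avg_methylation: float = np.nan

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())


def homogenize_fragment(
    reads: pd.DataFrame,
    fragment_id: str,
    ncpg: int = 5,
) -> Optional[PatternSet]:
    """Project reads onto the fragment's most-covered CpGs.

    ``reads`` is long-format: read_id, pos, call (1 = methylated).  The
    ``ncpg`` most-covered CpG positions are selected (coverage ties break
    to the leftmost genomic position); reads failing to cover all
    selected positions are dropped.  Fragments with fewer than ``ncpg``
    CpGs are excluded (returns None).
    """
    if reads.empty:
        return None
    cov = reads.groupby("pos")["read_id"].nunique()
    if len(cov) < ncpg:
        return None
    ranked = cov.reset_index().sort_values(
        ["read_id", "pos"], ascending=[False, True], kind="stable"
    )
    selected = sorted(ranked["pos"].head(ncpg).tolist())

    sub = reads[reads["pos"].isin(selected)]
    wide = sub.pivot_table(index="read_id", columns="pos", values="call",
                           aggfunc="first")
    wide = wide.reindex(columns=selected).dropna()
    counts: dict[str, int] = {}
    for row in wide.itertuples(index=False):
        pat = "".join(str(int(v)) for v in row)
        counts[pat] = counts.get(pat, 0) + 1
    return PatternSet(fragment_id, selected, counts)


def downsample_patterns(
    pattern_set: PatternSet,
    depth: int = 30,
    seed: int = 0,
    with_replacement: bool = False,
) -> PatternSet:
    """Downsample a homogenized pattern multiset to exactly ``depth`` reads.

    Sampling is uniform without replacement over the read multiset (a
    with-replacement mode is available); fragments with fewer than
    ``depth`` homogenized reads are marked uncovered.  The average
    methylation is always recomputed from the downsampled set.
    """
    total = pattern_set.n_reads
    if total < depth:
        return PatternSet(
            pattern_set.fragment_id, pattern_set.positions, {},
            downsampled=True, uncovered=True,
        )
    pats = sorted(pattern_set.counts)
    pool = np.repeat(
        np.arange(len(pats)), [pattern_set.counts[p] for p in pats]
    )
    rng = np.random.default_rng(seed)
    take = rng.choice(pool, size=depth, replace=with_replacement)
    counts: dict[str, int] = {}
    for i in take:
        counts[pats[i]] = counts.get(pats[i], 0) + 1
    ncpg = len(pats[0]) if pats else 0
    meth_calls = sum(c * p.count("1") for p, c in counts.items())
    avg = meth_calls / (depth * ncpg) if ncpg else np.nan
    return PatternSet(
        pattern_set.fragment_id, pattern_set.positions, counts,
        downsampled=True, avg_methylation=avg,
    )


def epipolymorphism(counts: dict[str, int] | np.ndarray, depth: int = 30) -> float:
    """Gini-Simpson diversity of epiallele frequencies: 1 - sum(p_i^2).

    Requires the counts to sum to the fixed depth (downsampling must run
    first) so values are comparable across fragments and tumors.
    """
    vals = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=float
    )
    total = vals.sum()
    if total != depth:
        raise ValueError(
            f"pattern counts sum to {total}, expected depth {depth}; "
            "downsample before computing epi-polymorphism"
        )
    p = vals / total
    return float(1.0 - np.sum(p * p))


def epipolymorphism_table(
    pattern_counts: pd.DataFrame,
    depth: int = 30,
    seed: int = 0,
    params: Parameters | None = None,
) -> pd.DataFrame:
    """Per-fragment epi-polymorphism from a pattern-count table.

    ``pattern_counts`` is indexed by fragment id with one column per
    epiallele pattern (``m00000`` .. ``m11111``).  Fragments with at
    least ``depth`` reads are downsampled to exactly ``depth``; fragments
    below are reported uncovered (NaN).
    """
    p = params or Parameters()
    depth = depth or p.epipoly_depth
    pat_cols = [c for c in pattern_counts.columns
                if c.startswith("m") and set(c[1:]) <= {"0", "1"}]
    ncpg = len(pat_cols[0]) - 1
    rows = []
    for i, (fid, row) in enumerate(pattern_counts[pat_cols].iterrows()):
        counts = {c[1:]: int(v) for c, v in row.items() if v > 0}
        ps = PatternSet(str(fid), [], counts)
        ds = downsample_patterns(ps, depth=depth, seed=seed + i)
        if ds.uncovered:
            rows.append({"fragment_id": fid, "epipolymorphism": np.nan,
                         "avg_methylation": np.nan, "n_reads": ps.n_reads})
        else:
            rows.append({
                "fragment_id": fid,
                "epipolymorphism": epipolymorphism(ds.counts, depth=depth),
                "avg_methylation": ds.avg_methylation,
                "n_reads": ps.n_reads,
            })
    return pd.DataFrame(rows).set_index("fragment_id")
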