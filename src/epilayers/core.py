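"""Core domain containers and pipeline parameters.

All genomic coordinates in this package are 0-based half-open.  Methylation
values are fractions in [0, 1] (NaN = missing); expression values are on a
log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import pandas as pd

LOCUS_CLASSES = ("promoter", "fragment", "enhancer")
GROUPS = ("ER+", "ER-", "normal")

#: metadata columns expected for loci, in canonical order
LOCUS_COLUMNS = ["chrom", "start", "end", "strand", "locus_class"]


@dataclass(frozen=True)
class Locus:
    """A genomic interval carrying the annotation the pipeline consumes."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    locus_class: str = "fragment"
    cpg_content: float = np.nan
    tor_value: float = np.nan
    tor_bin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval {self.start}..{self.end}")
        if self.locus_class not in LOCUS_CLASSES:
            raise ValueError(f"unknown locus class {self.locus_class!r}")
        if np.isfinite(self.cpg_content) and not 0 <= self.cpg_content <= 1:
            raise ValueError("cpg_content must lie in [0, 1]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class _Matrix:
    """Feature x sample value matrix with aligned feature metadata."""

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame):
        if not values.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if not values.index.equals(meta.index):
            meta = meta.loc[values.index]
        self.values = values.astype(np.float64)
        self._meta = meta

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples) -> "_Matrix":
        return type(self)(self.values[list(samples)], self._meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{type(self).__name__}({self.values.shape[0]} features x "
            f"{self.values.shape[1]} samples)"
        )


class MethylMatrix(_Matrix):
    """Per-locus methylation fractions with locus coordinates and class.

    ``loci`` holds at least chrom/start/end/strand/locus_class and may carry
    cpg_content, tor_value, tor_bin, tss_distance.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        loci: pd.DataFrame,
        coverage: Optional[pd.DataFrame] = None,
    ):
        vals = values.to_numpy(dtype=np.float64, na_value=np.nan)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("methylation fractions must lie in [0, 1]")
        super().__init__(values, loci)
        self.coverage = coverage

    @property
    def loci(self) -> pd.DataFrame:
        return self._meta

    def subset_class(self, locus_class: str) -> "MethylMatrix":
        keep = self._meta["locus_class"] == locus_class
        return MethylMatrix(self.values.loc[keep], self._meta.loc[keep])

    def subset_loci(self, ids) -> "MethylMatrix":
        ids = list(ids)
        return MethylMatrix(self.values.loc[ids], self._meta.loc[ids])

    def subset_samples(self, samples) -> "MethylMatrix":
        cov = self.coverage[list(samples)] if self.coverage is not None else None
        return MethylMatrix(self.values[list(samples)], self._meta, cov)


class ExprMatrix(_Matrix):
    """Log-scale expression per gene, with TSS coordinates in ``genes``."""

    def __init__(self, values: pd.DataFrame, genes: pd.DataFrame):
        super().__init__(values, genes)

    @property
    def genes(self) -> pd.DataFrame:
        return self._meta

    def subset_genes(self, ids) -> "ExprMatrix":
        ids = list(ids)
        return ExprMatrix(self.values.loc[ids], self._meta.loc[ids])


@dataclass
class SampleMetadata:
    """Per-sample annotations: group, grade, and optional genomic features."""

    table: pd.DataFrame  # index = sample id; columns include "group"
    cn_states: Optional[pd.DataFrame] = None  # genes x samples, values in {1..4}
    mutations: Optional[pd.DataFrame] = None  # features x samples, binary

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValueError("sample table requires a 'group' column")
        bad = set(self.table["group"].dropna()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")
        if "cin" in self.table.columns:
            cin = self.table["cin"].dropna()
            if len(cin) and (cin.min() < 0 or cin.max() > 1):
                raise ValueError("CIN must lie in [0, 1]")

    def samples_in_group(self, group: str) -> pd.Index:
        return self.table.index[self.table["group"] == group]


@dataclass
class Parameters:
    """Every tunable constant of the pipeline, with its default value.

    Defaults reproduce the published analysis settings; any field can be
    overridden per run (YAML config or keyword).
    """

    promoter_upstream: int = 500
    promoter_downstream: int = 50
    active_promoter_expr_threshold: float = 7.0
    meth_mean_bounds: tuple[float, float] = (0.1, 0.9)
    corr_floor: float = 0.25
    tme_corr_threshold: float = -0.3
    knn_k: dict = field(default_factory=lambda: {"ER+": 30, "ER-": 15, "normal": 15})
    n_cross_clusters: int = 30
    n_layer_clusters: int = 3
    layer_sample_size: int = 50_000
    enhancer_link_threshold: float = 0.25
    trans_cluster_threshold: float = 0.3
    mg_ml_locus_threshold: float = 0.5
    clock_locus_threshold: float = 0.6
    layer_mean_bound: float = 0.1
    layer_filter_on_normalized: bool = True
    min_corr_samples: int = 50
    distal_window: int = 500_000
    distal_promoter_margin: int = 2_000
    epipoly_ncpg: int = 5
    epipoly_depth: int = 30
    enhancer_top_quantile: float = 0.03
    enhancer_promoter_exclusion: int = 2_000
    enhancer_width: int = 200
    tor_late_quantile: float = 0.20
    tor_early_quantile: float = 0.60
    n_mut_strata: int = 5
    min_group_size: int = 20
    min_cn_stratum: int = 10
    zscore_signature_axes: bool = True
    weighted_promoter_mean: bool = True
    rng_seed: int = 0

    def override(self, **kwargs) -> "Parameters":
        known = {f.name for f in fields(self)}
        bad = set(kwargs) - known
        if bad:
            raise ValueError(f"unknown parameters: {sorted(bad)}")
        return replace(self, **kwargs)

    def knn_k_for(self, group: str) -> int:
        return int(self.knn_k[group])
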