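"""Tab-separated I/O for the pipeline's matrices and annotations.

All tables are gzip-transparent (by file extension), use "NA" as the
missing-value token, and are written with a fixed numeric format so that
reruns under the same seed are byte-identical.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import ExprMatrix, MethylMatrix, SampleMetadata

NA_TOKEN = "NA"
FLOAT_FORMAT = "%.6g"

_METH_META = ["chrom", "start", "end", "strand", "locus_class"]
_METH_OPTIONAL = ["cpg_content", "tor_value", "tor_bin", "tss_distance", "normal_mean"]
_EXPR_META = ["chrom", "tss", "strand"]


def _open_write(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _write_table(
    df: pd.DataFrame,
    path: str | Path,
    header_lines: Iterable[str] = (),
    index_label: str | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with _open_write(path) as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(
            fh,
            sep="\t",
            na_rep=NA_TOKEN,
            float_format=FLOAT_FORMAT,
            index=index_label is not None,
            index_label=index_label,
        )


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[NA_TOKEN], keep_default_na=False,
        **kwargs,
    )


def write_methyl_matrix(
    mm: MethylMatrix, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    meta_cols = _METH_META + [c for c in _METH_OPTIONAL if c in mm.loci.columns]
    df = pd.concat([mm.loci[meta_cols], mm.values], axis=1)
    _write_table(df, path, header_lines, index_label="locus_id")


def read_methyl_matrix(path: str | Path) -> MethylMatrix:
    df = _read_table(path, index_col="locus_id")
    meta_cols = [c for c in _METH_META + _METH_OPTIONAL if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    return MethylMatrix(df[sample_cols], df[meta_cols])


def write_expr_matrix(
    em: ExprMatrix, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    meta_cols = [c for c in _EXPR_META if c in em.genes.columns]
    df = pd.concat([em.genes[meta_cols], em.values], axis=1)
    _write_table(df, path, header_lines, index_label="gene")


def read_expr_matrix(path: str | Path) -> ExprMatrix:
    df = _read_table(path, index_col="gene")
    meta_cols = [c for c in _EXPR_META if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    return ExprMatrix(df[sample_cols], df[meta_cols])


def write_sample_metadata(
    sm: SampleMetadata, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    _write_table(sm.table, path, header_lines, index_label="sample")


def read_sample_metadata(
    path: str | Path,
    cn_path: str | Path | None = None,
    mutation_path: str | Path | None = None,
) -> SampleMetadata:
    table = _read_table(path, index_col="sample")
    cn = _read_table(cn_path, index_col=0) if cn_path else None
    mut = _read_table(mutation_path, index_col=0) if mutation_path else None
    return SampleMetadata(table, cn_states=cn, mutations=mut)


def write_frame(
    df: pd.DataFrame,
    path: str | Path,
    header_lines: Iterable[str] = (),
    index_label: str | None = None,
) -> None:
    """Generic deterministic TSV writer for result tables."""
    _write_table(df, path, header_lines, index_label=index_label)


def read_frame(path: str | Path, index_col=None) -> pd.DataFrame:
    return _read_table(path, index_col=index_col)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ reader; returns chrom/start/end (+name when present)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    with _open_write(Path(path)) as fh:
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """bedGraph reader: chrom/start/end/value."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = ["chrom", "start", "end", "value"] + list(df.columns[4:])
    return df


# ---------------------------------------------------------------------------
# read-level epiallele pattern tables
# ---------------------------------------------------------------------------

def pattern_columns(ncpg: int = 5) -> list[str]:
    """Column names for the 2**ncpg epiallele patterns, e.g. ``m01011``."""
    return [f"m{i:0{ncpg}b}" for i in range(2 ** ncpg)]


def write_pattern_table(
    df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    """Write per-fragment epiallele counts.

    Expected columns: fragment_id, sample (optional), chrom, start, end,
    cpg_positions (comma-joined), then one count column per pattern.
    """
    _write_table(df, path, header_lines)


def read_pattern_table(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    pat_cols = [c for c in df.columns if c.startswith("m") and set(c[1:]) <= {"0", "1"}]
    df[pat_cols] = df[pat_cols].fillna(0).astype(np.int64)
    return df
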