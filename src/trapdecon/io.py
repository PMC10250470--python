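"""Readers and writers for the delimited-text formats the pipeline consumes.

Canonical interchange is TSV (genes x samples with a header row of sample
identifiers and gene identifiers in the first column); comma-separated input
is accepted via ``sep=","``. Gene panels travel as GMT. Sample metadata is a
separate small table (sample, condition[, timepoint]) rather than being
encoded in matrix headers. All paths may be gzip-compressed (``.gz``).

Validation is strict at the boundary: duplicated gene identifiers, non-numeric
cells and negative values are rejected with errors that name the offending
gene / cell, per the data-model invariants.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ExpressionMatrix, GeneAnnotation, GeneSet

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_sample_metadata",
    "read_gene_annotation",
    "read_library_sizes",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression_table(
    path,
    unit: str = "fpkm",
    sample_meta=None,
    sep: str = "\t",
) -> ExpressionMatrix | CountMatrix:
    """Read a gene-by-sample matrix from delimited text.

    Parameters
    ----------
    path
        Delimited text file (optionally ``.gz``): first column gene
        identifiers, header row sample identifiers.
    unit
        ``counts`` yields a :class:`CountMatrix` (values must be integral);
        any other recognised unit tag yields an :class:`ExpressionMatrix`.
    sample_meta
        Optional path to a sample-metadata TSV (see
        :func:`read_sample_metadata`) or an already-loaded DataFrame.
    sep
        Field delimiter; tab by default, pass ``","`` for CSV.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene identifier in {path}: {dup!r}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if len(bad):
        g, s = bad[0]
        raise ValueError(
            f"non-numeric cell in {path} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}: {raw.iat[g, s]!r}"
        )
    arr = numeric.to_numpy()
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative value in {path} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )

    meta = None
    if sample_meta is not None:
        meta = (
            sample_meta
            if isinstance(sample_meta, pd.DataFrame)
            else read_sample_metadata(sample_meta)
        )

    if unit == "counts":
        return CountMatrix(numeric, sample_meta=meta)
    return ExpressionMatrix(numeric, unit=unit, sample_meta=meta)


def write_expression_table(matrix: ExpressionMatrix | CountMatrix, path, sep: str = "\t") -> None:
    """Write a matrix as delimited text (round-trips through the reader)."""
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep=sep)


def read_sample_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Read a sample metadata table: columns sample, condition[, timepoint]."""
    meta = pd.read_csv(path, sep=sep, dtype=str)
    if "sample" not in meta.columns or "condition" not in meta.columns:
        raise ValueError(f"{path}: metadata needs 'sample' and 'condition' columns")
    meta = meta.set_index("sample")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"duplicate sample identifier in {path}: {dup!r}")
    return meta


def read_gene_annotation(path, sep: str = "\t") -> GeneAnnotation:
    """Read gene lengths (and optional symbols) from a 2- or 3-column table.

    Columns: gene identifier, transcript length in bp[, symbol]. A header row
    is detected by a non-numeric second field on the first line.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, header=None, keep_default_na=False)
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    genes = df.iloc[:, 0].astype(str)
    lengths = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if lengths.isna().any():
        bad = genes[lengths.isna()].iloc[0]
        raise ValueError(f"{path}: non-numeric length for gene {bad!r}")
    lengths.index = genes
    symbols = None
    if df.shape[1] > 2:
        symbols = df.iloc[:, 2].astype(str)
        symbols.index = genes
    return GeneAnnotation(lengths=lengths, symbols=symbols)


def read_library_sizes(path, sep: str = "\t") -> pd.Series:
    """Read per-sample mapped-read totals from a 2-column table."""
    df = pd.read_csv(path, sep=sep, dtype=str, header=None, keep_default_na=False)
    try:
        float(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    sizes = pd.to_numeric(df.iloc[:, 1], errors="raise").astype(float)
    sizes.index = df.iloc[:, 0].astype(str)
    return sizes


def read_gene_sets(path, role: str = "pathway") -> list[GeneSet]:
    """Parse gene sets from GMT: per line, name TAB description TAB members...

    Members are deduplicated preserving insertion order. A line with fewer
    than three fields, or no members left after deduplication, is an error
    reported with its (1-based) line number.
    """
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, description=description,
                                members=tuple(members), role=role))
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with _open_text(path, "wt") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")
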