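"""Core data containers for translatome analysis.

The substrate of every statistic in this package is a gene-by-sample matrix:
integer read counts upstream (``CountMatrix``) and nonnegative real expression
values (FPKM or normalized protein intensity, ``ExpressionMatrix``) downstream.
Both are thin, validating wrappers around a :class:`pandas.DataFrame` with
genes as the row index and samples as columns, plus optional per-sample
metadata (condition and timepoint labels).

Validation happens at construction: duplicate identifiers, negative, missing
or non-finite values are rejected with an error naming the offending entity,
so downstream code can assume the invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CountMatrix",
    "GeneAnnotation",
    "GeneSet",
    "VALID_UNITS",
]

#: Recognised unit tags for an :class:`ExpressionMatrix`.
VALID_UNITS = ("fpkm", "normalized_intensity", "arbitrary")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} identifier: {dup!r}")


def _check_sample_meta(meta: pd.DataFrame, samples: pd.Index) -> pd.DataFrame:
    if "condition" not in meta.columns:
        raise ValueError("sample metadata must have a 'condition' column")
    missing = samples.difference(meta.index)
    if len(missing):
        raise ValueError(f"sample(s) missing from metadata: {list(missing)}")
    if meta.loc[samples, "condition"].isna().any():
        bad = meta.loc[samples, "condition"].isna()
        raise ValueError(
            f"sample(s) without a condition label: {list(samples[bad.values])}"
        )
    aligned = meta.loc[samples]
    aligned.index.name = meta.index.name or "sample"
    return aligned


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of nonnegative, finite expression values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as index and sample identifiers as
        columns. Values must be nonnegative and finite.
    unit
        One of ``fpkm``, ``normalized_intensity`` or ``arbitrary``.
    sample_meta
        Optional DataFrame indexed by sample with at least a ``condition``
        column; must cover every sample of ``data``.
    """

    data: pd.DataFrame
    unit: str = "arbitrary"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(
                f"unknown unit tag {self.unit!r}; expected one of {VALID_UNITS}"
            )
        self.data = self.data.astype(float, copy=False)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        arr = self.data.to_numpy()
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[g]!r}, sample {self.data.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                "negative expression value at gene "
                f"{self.data.index[g]!r}, sample {self.data.columns[s]!r}"
            )
        if self.sample_meta is not None:
            self.sample_meta = _check_sample_meta(self.sample_meta, self.data.columns)

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``genes`` (order preserved)."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"gene(s) absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[list(genes)], unit=self.unit, sample_meta=self.sample_meta
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"sample(s) absent from matrix: {missing[:5]}")
        meta = self.sample_meta.loc[list(samples)] if self.sample_meta is not None else None
        return ExpressionMatrix(self.data[list(samples)], unit=self.unit, sample_meta=meta)

    def samples_in(self, condition: str) -> list[str]:
        """Sample identifiers whose metadata condition equals ``condition``."""
        if self.sample_meta is None:
            raise ValueError("matrix carries no sample metadata")
        mask = self.sample_meta["condition"] == condition
        return list(self.sample_meta.index[mask])

    def with_data(self, data: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        """New matrix sharing this one's metadata but with different values."""
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(data.columns)]
        return ExpressionMatrix(data, unit=unit or self.unit, sample_meta=meta)


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of nonnegative integer read counts."""

    data: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.isfinite(arr).all() or not np.equal(np.mod(arr, 1), 0).all():
                bad = np.argwhere(~(np.isfinite(arr) & (np.mod(arr, 1) == 0)))[0]
                raise ValueError(
                    "non-integral count at gene "
                    f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
                )
            self.data = self.data.astype(np.int64)
            arr = self.data.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.data.index[g]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if self.sample_meta is not None:
            self.sample_meta = _check_sample_meta(self.sample_meta, self.data.columns)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


@dataclass
class GeneAnnotation:
    """Per-gene transcript length (bp, strictly positive) and optional symbol."""

    lengths: pd.Series
    symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        self.lengths = self.lengths.astype(float)
        _check_unique(self.lengths.index, "gene")
        if (self.lengths <= 0).any() or not np.isfinite(self.lengths).all():
            bad = self.lengths.index[~((self.lengths > 0) & np.isfinite(self.lengths))][0]
            raise ValueError(f"non-positive transcript length for gene {bad!r}")

    def lengths_for(self, genes) -> pd.Series:
        """Lengths for ``genes``; error naming the first gene not annotated."""
        missing = [g for g in genes if g not in self.lengths.index]
        if missing:
            raise KeyError(f"gene missing from annotation: {missing[0]!r}")
        return self.lengths.loc[list(genes)]


#: Recognised roles for a gene set.
GENESET_ROLES = (
    "contamination_marker",
    "celltype_marker",
    "phenotype_panel",
    "pathway",
)


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated panel of gene identifiers.

    Used for the negative-marker panel that drives contamination estimation
    (genes specific to non-astrocyte cell types, expected absent from a pure
    astrocyte translatome) as well as phenotype and pathway panels.
    """

    name: str
    description: str = ""
    members: tuple[str, ...] = field(default_factory=tuple)
    role: str = "pathway"

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m, None)
        object.__setattr__(self, "members", tuple(seen))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if self.role not in GENESET_ROLES:
            raise ValueError(f"unknown gene-set role {self.role!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def present_in(self, matrix: ExpressionMatrix | CountMatrix) -> list[str]:
        """Members found in the matrix, in panel order."""
        idx = set(matrix.data.index)
        return [m for m in self.members if m in idx]
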