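"""Deterministic normalizations.

Three operations, all closed-form:

* counts -> FPKM (fragments per kilobase of transcript per million mapped
  reads), ``fpkm(g, s) = counts(g, s) * 1e9 / (length(g) * libsize(s))``;
* proteomics total-intensity normalization — each protein's intensity divided
  by the summed intensity of all proteins in that sample, so columns sum to 1;
* per-gene log2 fold change between two sample groups on group means, with an
  explicit (default zero) pseudocount.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ExpressionMatrix, GeneAnnotation

__all__ = ["fpkm_from_counts", "total_intensity_normalize", "log2_fold_change"]


def fpkm_from_counts(
    counts: CountMatrix,
    annot: GeneAnnotation,
    library_sizes: pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert read counts to FPKM.

    Parameters
    ----------
    counts
        Gene-by-sample integer counts.
    annot
        Supplies the transcript length (bp) for every gene in ``counts``.
    library_sizes
        Per-sample mapped-read totals. When omitted, each sample's library
        size defaults to its column sum of counts, which makes the conversion
        self-contained and preserves the mass balance
        ``sum_g fpkm(g,s) * length(g) / 1e9 * libsize(s) == column total``.
    """
    lengths = annot.lengths_for(counts.genes)
    if library_sizes is None:
        library_sizes = counts.data.sum(axis=0).astype(float)
    else:
        missing = [s for s in counts.samples if s not in library_sizes.index]
        if missing:
            raise KeyError(f"sample missing from library sizes: {missing[0]!r}")
        library_sizes = library_sizes.loc[list(counts.samples)].astype(float)
    if (library_sizes <= 0).any():
        bad = library_sizes.index[library_sizes <= 0][0]
        raise ValueError(f"zero or negative library size for sample {bad!r}")

    vals = counts.data.to_numpy(dtype=float)
    fpkm = vals * 1e9 / (lengths.to_numpy()[:, None] * library_sizes.to_numpy()[None, :])
    df = pd.DataFrame(fpkm, index=counts.genes, columns=counts.samples)
    return ExpressionMatrix(df, unit="fpkm", sample_meta=counts.sample_meta)


def total_intensity_normalize(intensities: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize each sample by its summed intensity across all proteins.

    Every column of the result sums to 1, removing per-sample differences in
    total recovered material; the operation is idempotent. A sample with no
    positive intensity has no defined normalization and is an error.
    """
    sums = intensities.data.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total intensity")
    df = intensities.data / sums
    return ExpressionMatrix(df, unit="normalized_intensity",
                            sample_meta=intensities.sample_meta)


def log2_fold_change(
    E: ExpressionMatrix,
    group_a,
    group_b,
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-gene log2((mean_a + pseudocount) / (mean_b + pseudocount)).

    Groups must be nonempty and disjoint sample subsets. With the default
    pseudocount of 0, a zero group mean for any gene is an error (naming the
    gene) that directs the caller to set a pseudocount — a silent default
    would change results invisibly.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both sample groups must be nonempty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"sample groups overlap: {sorted(overlap)}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")

    mean_a = E.subset_samples(group_a).data.mean(axis=1)
    mean_b = E.subset_samples(group_b).data.mean(axis=1)
    if pseudocount == 0:
        zero = (mean_a == 0) | (mean_b == 0)
        if zero.any():
            gene = mean_a.index[zero][0]
            raise ValueError(
                f"zero group mean for gene {gene!r} with pseudocount 0; "
                "set a positive pseudocount to compute its fold change"
            )
    # difference of logs rather than log of ratio: antisymmetric to the bit
    return np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
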