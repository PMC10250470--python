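"""Background-mRNA contamination detection and exclusion for TRAP-seq.

Translating ribosome affinity purification (TRAP) enriches the translatome of
one cell type — here astrocytes — but pull-downs carry a variable amount of
background mRNA from other cell types. This module estimates that background
and removes the genes whose apparent signal it explains, in four steps:

1. For each *negative marker* gene (specific to a non-astrocyte cell type and
   expected absent from a pure astrocyte translatome), divide its expression
   in each sample by its maximum across samples, giving per-sample fractions
   ``c(g, s)`` in [0, 1].
2. Average the fractions over the marker panel to obtain the per-sample
   contamination measure ``C(s)`` in [0, 1].
3. For every non-marker gene, correlate its expression across samples with
   ``C`` (Pearson by default), giving the per-gene statistic ``R``. A null
   distribution of ``R`` is built by independently scrambling each gene's
   values between samples and recomputing ``R``; the gene's ``Z`` score is its
   distance from the null mean in null standard deviations.
4. Exclude every gene with ``Z`` strictly greater than a threshold
   (default 2) — contamination inflates only positive correlation with ``C``,
   so the exclusion is one-sided.

The model/results split follows statsmodels: :class:`ContaminationModel` holds
the data and configuration, ``fit()`` performs steps 1–3 and returns a
:class:`ContaminationResults` carrying the profile, scores, null distribution
and filtering.

Reproducibility contract — the scrambled null is generated from
``numpy.random.default_rng(seed)`` by iterating the scored (non-marker) genes
in matrix row order, skipping zero-variance genes, and drawing
``n_scrambles`` sample permutations per gene with ``rng.permutation(n)``.
This stream is part of the public contract so an independent implementation
can reproduce the null bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ExpressionMatrix, GeneSet

__all__ = [
    "ContaminationModel",
    "ContaminationResults",
    "ContaminationProfile",
    "NullDistribution",
    "FilterReport",
    "compute_contamination_profile",
    "compute_gene_scores",
    "apply_contamination_filter",
]


@dataclass
class ContaminationProfile:
    """Per-marker fractions c(g, s) and the per-sample contamination measure C."""

    markers_used: list[str]
    dropped_markers: dict[str, str]
    fractions: pd.DataFrame  # markers x samples, each row max-normalized to 1
    C: pd.Series  # per-sample mean of fractions over retained markers


@dataclass
class NullDistribution:
    """Pooled R statistics from sample-scrambled expression."""

    values: np.ndarray
    n_scrambles: int
    seed: int
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(self.values.mean())
        # sample sd (ddof=1): the null is a finite sample of scrambled R values
        self.sd = float(self.values.std(ddof=1))


@dataclass
class FilterReport:
    """What the Z filter removed and kept."""

    z_threshold: float
    excluded: pd.DataFrame  # index gene, columns R, Z
    n_retained: int
    marker_genes: list[str]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _corr_rows_with(X: np.ndarray, c: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row of X with vector c (rows assumed non-constant)."""
    if method == "spearman":
        X = sps.rankdata(X, axis=1)
        c = sps.rankdata(c)
    Xc = X - X.mean(axis=1, keepdims=True)
    cc = c - c.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (cc * cc).sum())
    return (Xc @ cc) / denom


def _corr_one(x: np.ndarray, c: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = sps.rankdata(x)
        c = sps.rankdata(c)
    xc = x - x.mean()
    cc = c - c.mean()
    return float((xc @ cc) / np.sqrt((xc * xc).sum() * (cc * cc).sum()))


class ContaminationModel:
    """Contamination model for an expression matrix and a negative-marker panel.

    Parameters
    ----------
    expression
        Gene-by-sample expression (FPKM); needs at least 3 samples for the
        correlation statistic to be non-trivial.
    markers
        Negative-marker panel. At least one member must be present in the
        matrix; members with all-zero expression are dropped with a warning.
    method
        Correlation flavour for R: ``pearson`` (default, the literal published
        procedure) or ``spearman`` (rank-robust alternative).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        markers: GeneSet,
        method: str = "pearson",
    ) -> None:
        if method not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation method {method!r}")
        self.expression = expression
        self.markers = markers
        self.method = method

    # -- step 1 + 2 ------------------------------------------------------------
    def contamination_profile(self) -> ContaminationProfile:
        """Max-normalize each marker and average into the per-sample C."""
        E = self.expression
        if E.n_samples < 2:
            raise ValueError("contamination profile needs at least 2 samples")
        present = self.markers.present_in(E)
        dropped: dict[str, str] = {}
        for m in self.markers.members:
            if m not in set(E.genes):
                dropped[m] = "absent from matrix"
        if not present:
            raise ValueError(
                f"no marker of panel {self.markers.name!r} present in the matrix"
            )
        rows = {}
        for m in present:
            x = E.data.loc[m].to_numpy(dtype=float)
            mx = x.max()
            if mx == 0:
                dropped[m] = "all-zero expression"
                warnings.warn(
                    f"marker {m!r} has zero expression in every sample; dropped",
                    stacklevel=2,
                )
                continue
            rows[m] = x / mx
        if not rows:
            raise ValueError(
                f"every marker of panel {self.markers.name!r} was dropped "
                "(all-zero expression)"
            )
        fractions = pd.DataFrame.from_dict(rows, orient="index", columns=E.samples)
        C = fractions.mean(axis=0)
        return ContaminationProfile(
            markers_used=list(rows), dropped_markers=dropped, fractions=fractions, C=C
        )

    # -- step 3 ----------------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        n_scrambles: int = 1,
        z_threshold: float = 2.0,
        profile: ContaminationProfile | None = None,
    ) -> "ContaminationResults":
        """Compute R for every non-marker gene, the scrambled null, and Z.

        ``n_scrambles`` independent sample permutations are drawn per gene and
        the resulting null R values pooled across genes. Identical seed and
        inputs give bit-identical results.
        """
        E = self.expression
        if E.n_samples < 3:
            raise ValueError("gene scoring needs at least 3 samples")
        if n_scrambles < 1:
            raise ValueError("n_scrambles must be a positive integer")
        if profile is None:
            profile = self.contamination_profile()
        c = profile.C.to_numpy(dtype=float)
        if np.ptp(c) == 0:
            raise ValueError(
                "contamination measure C is constant across samples; "
                "the contamination signal is undefined"
            )

        marker_ids = set(self.markers.members)
        scored_genes = [g for g in E.genes if g not in marker_ids]
        X = E.data.loc[scored_genes].to_numpy(dtype=float)
        n = E.n_samples

        degenerate = np.ptp(X, axis=1) == 0
        R = np.zeros(len(scored_genes))
        if (~degenerate).any():
            R[~degenerate] = _corr_rows_with(X[~degenerate], c, self.method)

        # scrambled null: one stream, row order, degenerate genes skipped
        rng = np.random.default_rng(seed)
        null_vals = []
        for i, _ in enumerate(scored_genes):
            if degenerate[i]:
                continue
            x = X[i]
            for _ in range(n_scrambles):
                perm = rng.permutation(n)
                null_vals.append(_corr_one(x[perm], c, self.method))
        if not null_vals:
            raise ValueError("no non-degenerate gene available to build the null")
        null = NullDistribution(np.array(null_vals), n_scrambles=n_scrambles, seed=seed)
        if null.sd == 0:
            raise ValueError("scrambled-null standard deviation is zero")

        Z = np.full(len(scored_genes), np.nan)
        Z[~degenerate] = (R[~degenerate] - null.mean) / null.sd
        scores = pd.DataFrame(
            {
                "R": R,
                "Z": Z,
                "degenerate": degenerate,
                "excluded": np.where(degenerate, False, Z > z_threshold),
            },
            index=pd.Index(scored_genes, name="gene"),
        )
        return ContaminationResults(
            model=self,
            profile=profile,
            null=null,
            scores=scores,
            z_threshold=z_threshold,
            seed=seed,
            n_scrambles=n_scrambles,
        )


@dataclass
class ContaminationResults:
    """Fitted contamination model: profile, per-gene scores and the null."""

    model: ContaminationModel
    profile: ContaminationProfile
    null: NullDistribution
    scores: pd.DataFrame  # index gene; columns R, Z, degenerate, excluded
    z_threshold: float
    seed: int
    n_scrambles: int

    @property
    def C(self) -> pd.Series:
        return self.profile.C

    def excluded_genes(self, z_threshold: float | None = None) -> list[str]:
        thr = self.z_threshold if z_threshold is None else z_threshold
        z = self.scores["Z"]
        mask = (~self.scores["degenerate"]) & (z > thr)
        return list(self.scores.index[mask])

    def filtered_matrix(
        self, z_threshold: float | None = None
    ) -> tuple[ExpressionMatrix, FilterReport]:
        """Remove genes with Z strictly above the threshold (one-sided).

        Marker genes are retained in the matrix (they were never scored) but
        listed in the report so downstream stages can drop them if configured.
        """
        thr = self.z_threshold if z_threshold is None else z_threshold
        E = self.model.expression
        missing = [g for g in self.scores.index if g not in set(E.genes)]
        if missing:
            raise ValueError(f"scores refer to genes absent from the matrix: {missing[:5]}")
        excluded = self.excluded_genes(thr)
        excluded_set = set(excluded)
        keep = [g for g in E.genes if g not in excluded_set]
        if not keep:
            warnings.warn(
                "every gene exceeded the Z threshold; filtered matrix is empty",
                stacklevel=2,
            )
        filtered = E.with_data(E.data.loc[keep])
        report = FilterReport(
            z_threshold=thr,
            excluded=self.scores.loc[excluded, ["R", "Z"]],
            n_retained=len(keep),
            marker_genes=[m for m in self.model.markers.members if m in set(E.genes)],
        )
        return filtered, report

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        excl = self.excluded_genes()
        lines = [
            "Contamination model results",
            "=" * 44,
            f"samples:            {self.model.expression.n_samples}",
            f"scored genes:       {len(self.scores)}",
            f"markers used:       {len(self.profile.markers_used)}"
            f" ({', '.join(self.profile.markers_used[:6])})",
            f"markers dropped:    {len(self.profile.dropped_markers)}",
            f"correlation:        {self.model.method}",
            f"null size:          {len(self.null.values)}"
            f" (n_scrambles={self.n_scrambles}, seed={self.seed})",
            f"null mean / sd:     {self.null.mean:+.4f} / {self.null.sd:.4f}",
            f"Z threshold:        > {self.z_threshold:g} (one-sided)",
            f"excluded genes:     {len(excl)}"
            f" ({100 * len(excl) / max(len(self.scores), 1):.1f}% of scored)",
            f"degenerate genes:   {int(self.scores['degenerate'].sum())}",
            "-" * 44,
            "per-sample contamination measure C:",
        ]
        lines += [f"  {s:<16s} {v:.4f}" for s, v in self.C.items()]
        return "\n".join(lines)


# -- functional surface --------------------------------------------------------

def compute_contamination_profile(
    E: ExpressionMatrix, markers: GeneSet
) -> ContaminationProfile:
    """Per-marker max-normalized fractions and the per-sample measure C."""
    return ContaminationModel(E, markers).contamination_profile()


def compute_gene_scores(
    E: ExpressionMatrix,
    profile: ContaminationProfile,
    markers: GeneSet,
    seed: int,
    n_scrambles: int = 1,
    method: str = "pearson",
    z_threshold: float = 2.0,
) -> tuple[pd.DataFrame, NullDistribution]:
    """Per-gene R and Z against the scrambled null; returns (scores, null)."""
    res = ContaminationModel(E, markers, method=method).fit(
        seed=seed, n_scrambles=n_scrambles, z_threshold=z_threshold, profile=profile
    )
    return res.scores, res.null


def apply_contamination_filter(
    E: ExpressionMatrix,
    scores: pd.DataFrame,
    markers: GeneSet,
    z_threshold: float = 2.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes whose Z exceeds the threshold (strict, one-sided)."""
    missing = [g for g in scores.index if g not in set(E.genes)]
    if missing:
        raise ValueError(f"scores refer to genes absent from the matrix: {missing[:5]}")
    z = scores["Z"]
    mask = (~scores["degenerate"]) & (z > z_threshold)
    excluded_idx = scores.index[mask]
    excluded_set = set(excluded_idx)
    keep = [g for g in E.genes if g not in excluded_set]
    if not keep:
        warnings.warn(
            "every gene exceeded the Z threshold; filtered matrix is empty",
            stacklevel=2,
        )
    filtered = E.with_data(E.data.loc[keep])
    report = FilterReport(
        z_threshold=z_threshold,
        excluded=scores.loc[excluded_idx, ["R", "Z"]],
        n_retained=len(keep),
        marker_genes=[m for m in markers.members if m in set(E.genes)],
    )
    return filtered, report
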