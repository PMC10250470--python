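"""Statistical summaries on expression matrices.

* ``ratio_paired_t_test`` — the two-tailed ratio paired t-test: a one-sample
  t-test of the paired log-ratios log(a_i/b_i) against zero. The result is
  invariant to the logarithm base (natural log internally).
* ``bh_adjust`` — Benjamini–Hochberg step-up FDR adjustment.
* ``DifferentialExpressionModel`` / ``differential_expression`` — a documented
  stand-in DE stage: per-gene Welch t-test on log2(expression + pseudocount),
  BH adjustment, and up/down calls at a symmetric fold-change threshold
  (default 1.3-fold) with adjusted p < alpha (default 0.05). This is
  deliberately not a negative-binomial GLM; the ``method`` field of every
  result labels it.
* ``expression_floor_filter`` — genes whose maximum expression exceeds a
  floor (default 5 FPKM, strict inequality).
* ``gene_set_summary`` — per-panel log2 fold changes and the ratio paired
  t-test over the panel's per-gene group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix, GeneSet
from .normalize import log2_fold_change

__all__ = [
    "TestResult",
    "DEResults",
    "GeneSetSummary",
    "DifferentialExpressionModel",
    "ratio_paired_t_test",
    "bh_adjust",
    "differential_expression",
    "expression_floor_filter",
    "gene_set_summary",
]

DE_METHOD_LABEL = "welch-t on log2(expression + pseudocount); BH adjustment"


@dataclass
class TestResult:
    """Outcome of a ratio paired t-test."""

    statistic: float
    df: int
    pvalue: float
    n_pairs: int
    mean_log_ratio: float  # natural-log scale
    se_log_ratio: float


def ratio_paired_t_test(a, b) -> TestResult:
    """Two-tailed ratio paired t-test of positive paired measurements.

    Tests whether the paired ratios a_i/b_i differ from 1 by a one-sample
    t-test of log(a_i/b_i) against 0: t = mean/(sd/sqrt(n)), df = n - 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("ratio paired t-test needs at least 2 pairs")
    nonpos = (a <= 0) | (b <= 0)
    if nonpos.any():
        i = int(np.argmax(nonpos))
        raise ValueError(
            f"nonpositive value in pair {i} (a={a[i]!r}, b={b[i]!r}); "
            "ratios require strictly positive measurements"
        )
    logr = np.log(a) - np.log(b)
    sd = logr.std(ddof=1)
    if sd == 0:
        raise ValueError("log-ratios have zero variance; the t-test is degenerate")
    mean = logr.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(statistic=float(t), df=n - 1, pvalue=float(p),
                      n_pairs=n, mean_log_ratio=float(mean), se_log_ratio=float(se))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        bad = int(np.argmax(~((p >= 0) & (p <= 1))))
        raise ValueError(f"p-value out of [0, 1] at position {bad}: {p[bad]!r}")
    return multipletests(p, method="fdr_bh")[1]


def expression_floor_filter(E: ExpressionMatrix, min_value: float = 5.0) -> list[str]:
    """Genes whose maximum expression across samples is strictly > min_value."""
    mx = E.data.max(axis=1)
    return list(E.genes[mx > min_value])


class DifferentialExpressionModel:
    """Stand-in differential expression between two sample groups.

    Per gene, a Welch (unequal-variance) two-sample t-test on
    log2(expression + pseudocount); BH adjustment across tested genes; calls
    ``up`` when log2FC >= log2(fc_threshold) and q < alpha, ``down``
    symmetrically, else ``ns``. The fold threshold is inclusive, the alpha
    strict. Genes with zero variance in both groups are untestable: p and q
    are NaN and the call is ``ns``.
    """

    def __init__(
        self,
        E: ExpressionMatrix,
        group_a,
        group_b,
        pseudocount: float = 1.0,
    ) -> None:
        group_a, group_b = list(group_a), list(group_b)
        if len(group_a) < 2 or len(group_b) < 2:
            raise ValueError("each group needs at least 2 samples")
        overlap = set(group_a) & set(group_b)
        if overlap:
            raise ValueError(f"sample groups overlap: {sorted(overlap)}")
        if pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        self.E = E
        self.group_a = group_a
        self.group_b = group_b
        self.pseudocount = pseudocount

    def fit(self, fc_threshold: float = 1.3, alpha: float = 0.05) -> "DEResults":
        A = self.E.subset_samples(self.group_a).data.to_numpy(dtype=float)
        B = self.E.subset_samples(self.group_b).data.to_numpy(dtype=float)
        pc = self.pseudocount

        logA = np.log2(A + pc) if pc > 0 else np.log2(A)
        logB = np.log2(B + pc) if pc > 0 else np.log2(B)
        if not (np.isfinite(logA).all() and np.isfinite(logB).all()):
            raise ValueError(
                "zero expression with pseudocount 0; set a positive pseudocount"
            )

        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = sps.ttest_ind(logA, logB, axis=1, equal_var=False)
        testable = np.isfinite(p)

        q = np.full(p.shape, np.nan)
        if testable.any():
            q[testable] = bh_adjust(p[testable])

        mean_a = A.mean(axis=1)
        mean_b = B.mean(axis=1)
        log2fc = np.log2(mean_a + pc) - np.log2(mean_b + pc)

        lfc_cut = np.log2(fc_threshold)
        sig = testable & (q < alpha)
        call = np.where(sig & (log2fc >= lfc_cut), "up",
                        np.where(sig & (log2fc <= -lfc_cut), "down", "ns"))

        frame = pd.DataFrame(
            {
                "mean_a": mean_a,
                "mean_b": mean_b,
                "log2fc": log2fc,
                "t": t,
                "pvalue": p,
                "qvalue": q,
                "call": call,
            },
            index=self.E.genes.copy(),
        )
        return DEResults(
            frame=frame,
            fc_threshold=fc_threshold,
            alpha=alpha,
            pseudocount=pc,
            group_a=self.group_a,
            group_b=self.group_b,
        )


@dataclass
class DEResults:
    """Per-gene differential-expression table plus call summary."""

    frame: pd.DataFrame
    fc_threshold: float
    alpha: float
    pseudocount: float
    group_a: list[str]
    group_b: list[str]
    method: str = DE_METHOD_LABEL

    @property
    def n_up(self) -> int:
        return int((self.frame["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["call"] == "down").sum())

    def summary(self) -> str:
        lines = [
            "Differential expression results (stand-in test)",
            "=" * 48,
            f"method:        {self.method}",
            f"group A:       {', '.join(self.group_a)}",
            f"group B:       {', '.join(self.group_b)}",
            f"genes tested:  {int(np.isfinite(self.frame['pvalue']).sum())}"
            f" of {len(self.frame)}",
            f"thresholds:    fold >= {self.fc_threshold:g} (|log2FC| >= "
            f"{np.log2(self.fc_threshold):.4f}), q < {self.alpha:g}",
            f"pseudocount:   {self.pseudocount:g}",
            f"up / down:     {self.n_up} / {self.n_down}",
        ]
        return "\n".join(lines)


def differential_expression(
    E: ExpressionMatrix,
    group_a,
    group_b,
    fc_threshold: float = 1.3,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> DEResults:
    """Functional wrapper over :class:`DifferentialExpressionModel`."""
    return DifferentialExpressionModel(E, group_a, group_b, pseudocount).fit(
        fc_threshold=fc_threshold, alpha=alpha
    )


@dataclass
class GeneSetSummary:
    """Fold-change summary of one gene panel between two conditions."""

    set_name: str
    log2fc: pd.Series  # per found member
    missing: list[str]
    mean_log2fc: float
    ttest: TestResult | None  # ratio paired t over per-gene group means


def gene_set_summary(
    E: ExpressionMatrix,
    gene_set: GeneSet,
    group_a,
    group_b,
    pseudocount: float = 0.0,
) -> GeneSetSummary:
    """Per-member log2 fold change and a ratio paired t-test over the panel.

    Fold changes come from :func:`trapdecon.normalize.log2_fold_change` on the
    panel's found members. The t-test pairs each found gene's group-A mean
    with its group-B mean (plus the pseudocount, which also guarantees
    positivity when set); panels with fewer than two found members carry no
    t-test. Missing members are always listed, never silently dropped.
    """
    found = gene_set.present_in(E)
    missing = [m for m in gene_set.members if m not in set(found)]
    if not found:
        raise ValueError(f"no member of gene set {gene_set.name!r} found in the matrix")
    sub = E.subset_genes(found)
    lfc = log2_fold_change(sub, group_a, group_b, pseudocount=pseudocount)
    mean_a = sub.subset_samples(list(group_a)).data.mean(axis=1) + pseudocount
    mean_b = sub.subset_samples(list(group_b)).data.mean(axis=1) + pseudocount
    ttest = None
    if len(found) >= 2:
        ma, mb = mean_a.to_numpy(), mean_b.to_numpy()
        positive = ((ma > 0) & (mb > 0)).all()
        if positive and np.ptp(np.log(ma) - np.log(mb)) == 0:
            warnings.warn(
                f"gene set {gene_set.name!r}: log-ratios of group means are "
                "constant; ratio paired t-test omitted",
                stacklevel=2,
            )
        else:
            ttest = ratio_paired_t_test(ma, mb)
    return GeneSetSummary(
        set_name=gene_set.name,
        log2fc=lfc,
        missing=missing,
        mean_log2fc=float(lfc.mean()),
        ttest=ttest,
    )
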