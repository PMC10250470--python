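"""Ratio paired t-test, BH adjustment, the DE stand-in, floor filter, panels."""

import numpy as np
import pandas as pd
import pytest

from oracles import bh_stepup_bruteforce
from trapdecon.datamodel import ExpressionMatrix, GeneSet
from trapdecon.normalize import log2_fold_change
from trapdecon.stats import (
    bh_adjust,
    differential_expression,
    expression_floor_filter,
    gene_set_summary,
    ratio_paired_t_test,
)


class TestRatioPairedT:
    def test_worked_example(self):
        res = ratio_paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 2.0])
        assert res.statistic == pytest.approx(6.13, abs=0.01)
        assert res.df == 2
        assert res.pvalue == pytest.approx(0.026, abs=0.001)
        assert res.n_pairs == 3

    def test_log_base_invariance(self):
        # the same one-sample t computed on log2 ratios by hand
        a = np.array([3.0, 5.0, 8.0, 2.5])
        b = np.array([1.5, 4.0, 3.0, 2.0])
        res = ratio_paired_t_test(a, b)
        logr2 = np.log2(a) - np.log2(b)
        t2 = logr2.mean() / (logr2.std(ddof=1) / np.sqrt(len(a)))
        assert res.statistic == pytest.approx(t2, rel=1e-12)

    def test_identical_pairs_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            ratio_paired_t_test([2.0, 3.0], [2.0, 3.0])

    def test_nonpositive_value_names_pair(self):
        with pytest.raises(ValueError, match="pair 1"):
            ratio_paired_t_test([2.0, 0.0, 3.0], [1.0, 1.0, 1.0])

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError, match="2 pairs"):
            ratio_paired_t_test([2.0], [1.0])


class TestBhAdjust:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="position 1"):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("n,seed", [(10, 0), (500, 1), (10_000, 2)])
    def test_matches_bruteforce_stepup(self, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(n)
        np.testing.assert_allclose(bh_adjust(p), bh_stepup_bruteforce(p), rtol=1e-12)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFloorFilter:
    def _E(self, maxima):
        n = len(maxima)
        df = pd.DataFrame(
            {"s1": [m / 2 for m in maxima], "s2": list(maxima)},
            index=[f"g{i}" for i in range(n)],
        )
        return ExpressionMatrix(df)

    def test_strict_inequality_at_floor(self):
        E = self._E([5.0, 5.01, 4.0])
        kept = expression_floor_filter(E, min_value=5.0)
        assert kept == ["g1"]

    def test_zero_floor_keeps_any_positive(self):
        E = self._E([0.0, 0.001])
        assert expression_floor_filter(E, min_value=0.0) == ["g1"]


class TestDifferentialExpression:
    def _matrix(self, rows, samples):
        return ExpressionMatrix(pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))], columns=samples))

    def test_planted_fourfold_called_up(self):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        rows = [
            [40.0, 40.4, 39.6, 10.0, 10.1, 9.9],   # true 4-fold up
            [10.0, 10.1, 9.9, 10.05, 9.95, 10.0],  # null
        ]
        res = differential_expression(self._matrix(rows, samples),
                                      samples[:3], samples[3:])
        assert res.frame.loc["g0", "call"] == "up"
        assert res.frame.loc["g1", "call"] == "ns"
        assert res.n_up == 1

    def test_significant_but_below_fold_threshold_is_ns(self):
        # ~1.29-fold (log2 ≈ 0.37 < log2 1.3 ≈ 0.3785) with tiny noise:
        # q is small but the fold gate keeps the call at ns
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        rows = [[12.93, 12.94, 12.92, 10.0, 10.01, 9.99]]
        res = differential_expression(self._matrix(rows, samples),
                                      samples[:3], samples[3:], pseudocount=0.0)
        assert res.frame.loc["g0", "qvalue"] < 0.05
        assert abs(res.frame.loc["g0", "log2fc"]) < np.log2(1.3)
        assert res.frame.loc["g0", "call"] == "ns"

    def test_null_data_raw_p_calibrated(self):
        rng = np.random.default_rng(12)
        X = np.exp(rng.normal(0.0, 0.5, (2000, 10))) * 20.0
        samples = [f"s{j}" for j in range(10)]
        E = self._matrix(X, samples)
        res = differential_expression(E, samples[:5], samples[5:], pseudocount=0.0)
        frac = float((res.frame["pvalue"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_untestable_genes_are_ns_with_nan_p(self):
        samples = ["a1", "a2", "b1", "b2"]
        rows = [[5.0, 5.0, 5.0, 5.0], [8.0, 9.0, 2.0, 2.5]]
        res = differential_expression(self._matrix(rows, samples),
                                      samples[:2], samples[2:])
        assert np.isnan(res.frame.loc["g0", "pvalue"])
        assert res.frame.loc["g0", "call"] == "ns"

    def test_group_validation(self):
        samples = ["a1", "a2", "b1", "b2"]
        E = self._matrix([[1.0, 2.0, 3.0, 4.0]], samples)
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(E, ["a1", "b1"], ["b1", "b2"])
        with pytest.raises(ValueError, match="2 samples"):
            differential_expression(E, ["a1"], ["b1", "b2"])

    def test_summary_labels_the_standin_method(self):
        samples = ["a1", "a2", "b1", "b2"]
        E = self._matrix([[1.0, 2.0, 3.0, 4.0]], samples)
        res = differential_expression(E, samples[:2], samples[2:])
        assert "welch" in res.summary().lower()


class TestGeneSetSummary:
    def _setup(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(10)]
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        df = pd.DataFrame(rng.exponential(20.0, (10, 6)) + 1.0,
                          index=genes, columns=samples)
        E = ExpressionMatrix(df)
        gs = GeneSet("panel", "", ("g1", "g3", "g5", "g7"))
        return E, gs, samples

    def test_equals_composition_of_suboperations(self):
        E, gs, samples = self._setup()
        summ = gene_set_summary(E, gs, samples[:3], samples[3:])
        sub = E.subset_genes(list(gs.members))
        lfc = log2_fold_change(sub, samples[:3], samples[3:])
        np.testing.assert_array_equal(summ.log2fc.to_numpy(), lfc.to_numpy())
        assert summ.mean_log2fc == pytest.approx(float(lfc.mean()))
        ma = sub.subset_samples(samples[:3]).data.mean(axis=1).to_numpy()
        mb = sub.subset_samples(samples[3:]).data.mean(axis=1).to_numpy()
        assert summ.ttest.statistic == pytest.approx(
            ratio_paired_t_test(ma, mb).statistic, rel=1e-12)

    def test_missing_members_listed(self):
        E, _, samples = self._setup()
        gs = GeneSet("panel", "", ("g1", "g2", "Absent1"))
        summ = gene_set_summary(E, gs, samples[:3], samples[3:])
        assert summ.missing == ["Absent1"]
        assert len(summ.log2fc) == 2
        assert len(summ.missing) + len(summ.log2fc) == len(gs)

    def test_equal_valued_groups_give_zero_lfc_no_ttest(self):
        genes = ["g1", "g2"]
        df = pd.DataFrame({"a1": [4.0, 8.0], "a2": [6.0, 2.0],
                           "b1": [4.0, 8.0], "b2": [6.0, 2.0]}, index=genes)
        E = ExpressionMatrix(df)
        gs = GeneSet("panel", "", ("g1", "g2"))
        with pytest.warns(UserWarning, match="constant"):
            summ = gene_set_summary(E, gs, ["a1", "a2"], ["b1", "b2"])
        assert list(summ.log2fc) == pytest.approx([0.0, 0.0])
        assert summ.ttest is None

    def test_no_member_found_is_error(self):
        E, _, samples = self._setup()
        gs = GeneSet("panel", "", ("X1", "X2"))
        with pytest.raises(ValueError, match="panel"):
            gene_set_summary(E, gs, samples[:3], samples[3:])
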