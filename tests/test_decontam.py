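"""The contamination measure C, gene statistic R, scrambled null, and Z filter."""

import numpy as np
import pandas as pd
import pytest

from oracles import decontam_chain_bruteforce
from trapdecon.datamodel import ExpressionMatrix, GeneSet
from trapdecon.decontam import (
    ContaminationModel,
    apply_contamination_filter,
    compute_contamination_profile,
    compute_gene_scores,
)


def _matrix(rows, genes, samples=None):
    samples = samples or [f"s{j + 1}" for j in range(len(rows[0]))]
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples))


def _markers(*names):
    return GeneSet("mk", "", tuple(names), role="contamination_marker")


class TestContaminationProfile:
    def test_single_marker_max_normalization(self):
        E = _matrix([[2.0, 4.0, 0.0]], ["m1"])
        prof = compute_contamination_profile(E, _markers("m1"))
        assert list(prof.fractions.loc["m1"]) == [0.5, 1.0, 0.0]
        assert list(prof.C) == [0.5, 1.0, 0.0]

    def test_two_marker_average(self):
        E = _matrix([[2.0, 4.0, 0.0], [3.0, 3.0, 3.0]], ["m1", "m2"])
        prof = compute_contamination_profile(E, _markers("m1", "m2"))
        assert list(prof.C) == pytest.approx([0.75, 1.0, 0.5])

    def test_retained_marker_rows_peak_at_one(self):
        rng = np.random.default_rng(0)
        E = _matrix(rng.exponential(2.0, (3, 5)), ["m1", "m2", "m3"])
        prof = compute_contamination_profile(E, _markers("m1", "m2", "m3"))
        np.testing.assert_array_equal(prof.fractions.max(axis=1).to_numpy(), 1.0)

    def test_all_zero_marker_dropped_with_warning(self):
        E = _matrix([[0.0, 0.0, 0.0], [1.0, 2.0, 4.0]], ["m1", "m2"])
        with pytest.warns(UserWarning, match="m1"):
            prof = compute_contamination_profile(E, _markers("m1", "m2"))
        assert prof.markers_used == ["m2"]
        assert "m1" in prof.dropped_markers
        assert list(prof.C) == [0.25, 0.5, 1.0]

    def test_no_marker_present_is_error(self):
        E = _matrix([[1.0, 2.0]], ["gA"])
        with pytest.raises(ValueError, match="no marker"):
            compute_contamination_profile(E, _markers("m1"))

    def test_every_marker_dropped_is_error(self):
        E = _matrix([[0.0, 0.0], [1.0, 2.0]], ["m1", "gA"])
        with pytest.raises(ValueError, match="dropped"):
            compute_contamination_profile(E, _markers("m1"))


class TestGeneScores:
    def test_gene_proportional_to_c_has_r_one(self):
        E = _matrix([[1.0, 4.0, 2.0, 1.0], [0.5, 2.0, 1.0, 0.5]], ["m1", "gA"])
        res = ContaminationModel(E, _markers("m1")).fit(seed=0)
        assert res.scores.loc["gA", "R"] == pytest.approx(1.0)

    def test_constant_gene_is_degenerate_and_never_excluded(self):
        E = _matrix(
            [[1.0, 4.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0], [3.0, 1.0, 4.0, 2.0]],
            ["m1", "gConst", "gB"],
        )
        res = ContaminationModel(E, _markers("m1")).fit(seed=0)
        row = res.scores.loc["gConst"]
        assert row["degenerate"]
        assert row["R"] == 0.0
        assert not row["excluded"]
        assert np.isnan(row["Z"])

    def test_markers_absent_from_score_table(self):
        E = _matrix(np.arange(12.0).reshape(3, 4) + 1.0, ["m1", "gA", "gB"])
        res = ContaminationModel(E, _markers("m1")).fit(seed=0)
        assert "m1" not in res.scores.index
        assert set(res.scores.index) == {"gA", "gB"}

    def test_matches_bruteforce_chain_exactly(self):
        rng = np.random.default_rng(21)
        E = _matrix(np.exp(rng.normal(0, 1, (6, 4))), [f"g{i}" for i in range(6)])
        markers = _markers("g0", "g1")
        res = ContaminationModel(E, markers).fit(seed=99, n_scrambles=1)
        C, R, null, Z = decontam_chain_bruteforce(E.data, list(markers.members), 99, 1)
        np.testing.assert_allclose(res.C.to_numpy(), C, atol=1e-12)
        for g in R:
            assert res.scores.loc[g, "R"] == pytest.approx(R[g], abs=1e-12)
            assert res.scores.loc[g, "Z"] == pytest.approx(Z[g], abs=1e-12)
        np.testing.assert_allclose(res.null.values, null, atol=1e-12)

    def test_determinism_same_seed_bit_identical(self, random_matrix):
        E, markers = random_matrix(40, 6, seed=2, n_markers=3)
        a = ContaminationModel(E, markers).fit(seed=5, n_scrambles=2)
        b = ContaminationModel(E, markers).fit(seed=5, n_scrambles=2)
        np.testing.assert_array_equal(a.scores["Z"].to_numpy(), b.scores["Z"].to_numpy())
        assert a.excluded_genes() == b.excluded_genes()

    def test_global_rescaling_leaves_c_r_z_unchanged(self, random_matrix):
        E, markers = random_matrix(30, 5, seed=7, n_markers=2)
        scaled = ExpressionMatrix(E.data * 2.0)
        a = ContaminationModel(E, markers).fit(seed=3)
        b = ContaminationModel(scaled, markers).fit(seed=3)
        np.testing.assert_array_equal(a.C.to_numpy(), b.C.to_numpy())
        np.testing.assert_array_equal(a.scores["R"].to_numpy(), b.scores["R"].to_numpy())
        np.testing.assert_array_equal(a.scores["Z"].to_numpy(), b.scores["Z"].to_numpy())

    def test_null_values_bounded_by_one(self, random_matrix):
        E, markers = random_matrix(50, 6, seed=9, n_markers=3)
        res = ContaminationModel(E, markers).fit(seed=1, n_scrambles=3)
        assert np.all(np.abs(res.null.values) <= 1 + 1e-12)
        assert res.null.sd >= 0

    def test_constant_c_is_error(self):
        E = _matrix([[3.0, 3.0, 3.0], [1.0, 2.0, 4.0]], ["m1", "gA"])
        with pytest.raises(ValueError, match="constant"):
            ContaminationModel(E, _markers("m1")).fit(seed=0)

    def test_spearman_option(self):
        E = _matrix([[1.0, 4.0, 2.0, 1.5], [10.0, 400.0, 30.0, 20.0]], ["m1", "gA"])
        res = ContaminationModel(E, _markers("m1"), method="spearman").fit(seed=0)
        assert res.scores.loc["gA", "R"] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        E = _matrix([[1.0, 2.0], [3.0, 1.0]], ["m1", "gA"])
        with pytest.raises(ValueError, match="3 samples"):
            ContaminationModel(E, _markers("m1")).fit(seed=0)


class TestFilter:
    def _scores(self, z):
        return pd.DataFrame(
            {
                "R": [0.0] * len(z),
                "Z": list(z.values()),
                "degenerate": [False] * len(z),
                "excluded": [v > 2 for v in z.values()],
            },
            index=list(z),
        )

    def test_strictly_greater_than_threshold(self):
        E = _matrix(np.arange(16.0).reshape(4, 4) + 1.0, ["g1", "g2", "g3", "m1"])
        scores = self._scores({"g1": 3.1, "g2": 1.9, "g3": -0.5})
        filtered, report = apply_contamination_filter(E, scores, _markers("m1"))
        assert list(filtered.genes) == ["g2", "g3", "m1"]
        assert list(report.excluded.index) == ["g1"]

    def test_z_exactly_at_threshold_retained(self):
        E = _matrix([[1.0, 2.0], [3.0, 4.0]], ["g1", "m1"])
        scores = self._scores({"g1": 2.0})
        filtered, report = apply_contamination_filter(E, scores, _markers("m1"))
        assert "g1" in set(filtered.genes)
        assert report.n_excluded == 0

    def test_markers_retained_but_reported(self):
        E = _matrix(np.arange(8.0).reshape(2, 4) + 1.0, ["gA", "m1"])
        scores = self._scores({"gA": 5.0})
        filtered, report = apply_contamination_filter(E, scores, _markers("m1"))
        assert list(filtered.genes) == ["m1"]
        assert report.marker_genes == ["m1"]

    def test_everything_excluded_warns_and_empties(self):
        E = _matrix([[1.0, 2.0], [2.0, 1.0]], ["g1", "g2"])
        scores = self._scores({"g1": 4.0, "g2": 3.0})
        with pytest.warns(UserWarning, match="empty"):
            filtered, report = apply_contamination_filter(E, scores, _markers("mX"))
        assert filtered.n_genes == 0
        assert report.n_excluded == 2

    def test_scores_for_unknown_genes_rejected(self):
        E = _matrix([[1.0, 2.0]], ["g1"])
        scores = self._scores({"g1": 0.0, "ghost": 9.0})
        with pytest.raises(ValueError, match="ghost"):
            apply_contamination_filter(E, scores, _markers("mX"))


def test_functional_surface_matches_model(random_matrix):
    """compute_* wrappers are exactly the model/results path."""
    E, markers = random_matrix(25, 5, seed=4, n_markers=2)
    prof = compute_contamination_profile(E, markers)
    scores, null = compute_gene_scores(E, prof, markers, seed=8, n_scrambles=2)
    res = ContaminationModel(E, markers).fit(seed=8, n_scrambles=2)
    np.testing.assert_array_equal(scores["Z"].to_numpy(), res.scores["Z"].to_numpy())
    np.testing.assert_array_equal(null.values, res.null.values)
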