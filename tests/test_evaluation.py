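"""Stratified splitting, accuracy bookkeeping and per-group allele frequencies."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin

import aimsel
from aimsel.evaluation import (
    SplitError,
    SplitSpec,
    allocate_test_counts,
    cross_validate,
    evaluate_split,
    minor_allele_frequency,
    repeat_splits,
    stratified_split,
)
from aimsel.io import MISSING


class LabelLeakClassifier(ClassifierMixin, BaseEstimator):
    """Predicts the label stored in the first feature column (perfect model)."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return self.classes_[np.asarray(X[:, 0], dtype=int)]


class MajorityClassifier(ClassifierMixin, BaseEstimator):
    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.majority_ = vals[np.argmax(counts)]
        self.classes_ = vals
        return self

    def predict(self, X):
        return np.repeat(self.majority_, len(X))


class TestSplitArithmetic:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (87, 13),   # 13.05 -> 13
            (110, 16),  # 16.5 rounds half-to-even to 16
            (165, 25),  # 24.75 -> 25
            (86, 13),   # 12.9 -> 13
        ],
    )
    def test_half_to_even_allocation(self, size, expected):
        assert allocate_test_counts({"g": size})["g"] == expected

    def test_tiny_fraction_allocates_zero(self):
        counts = allocate_test_counts({"g": 5}, test_fraction=0.01)
        assert counts["g"] == 0

    def test_split_is_deterministic_and_conserving(self):
        labels = np.array(["a"] * 40 + ["b"] * 25)
        tr1, te1 = stratified_split(labels, SplitSpec(0.15, 5))
        tr2, te2 = stratified_split(labels, SplitSpec(0.15, 5))
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(te1, te2)
        assert len(tr1) + len(te1) == 65
        assert np.intersect1d(tr1, te1).size == 0
        # 40 * .15 = 6 test; 25 * .15 = 3.75 -> 4 test
        assert (labels[te1] == "a").sum() == 6
        assert (labels[te1] == "b").sum() == 4

    def test_group_fully_allocated_to_test_is_an_error(self):
        labels = np.array(["a"] * 40 + ["b"])
        with pytest.raises(SplitError, match="no training samples"):
            stratified_split(labels, SplitSpec(0.9, 0))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=0.0)
        with pytest.raises(ValueError):
            SplitSpec(test_fraction=1.0)


class TestCrossValidate:
    def test_perfect_classifier_scores_one_everywhere(self):
        y = np.array(["a"] * 20 + ["b"] * 20)
        X = np.array([0] * 20 + [1] * 20, dtype=float).reshape(-1, 1)
        report = cross_validate(X, y, LabelLeakClassifier(), n_folds=5, seed=0)
        assert report.total_accuracy == 1.0
        assert (report.per_group_accuracy == 1.0).all()

    def test_every_sample_predicted_exactly_once(self):
        y = np.array(["a"] * 20 + ["b"] * 30)
        X = np.zeros((50, 1))
        report = cross_validate(X, y, MajorityClassifier(), n_folds=5, seed=0)
        assert report.confusion.to_numpy().sum() == 50
        assert report.n_per_group.sum() == 50

    def test_majority_dummy_equals_largest_class_share(self):
        # 12 'a' vs 8 'b': majority is always 'a' in every fold of a
        # stratified CV, so Q = 12/20 exactly by hand tally.
        y = np.array(["a"] * 12 + ["b"] * 8)
        X = np.zeros((20, 1))
        report = cross_validate(X, y, MajorityClassifier(), n_folds=4, seed=1)
        assert report.total_accuracy == pytest.approx(12 / 20)
        assert report.per_group_accuracy["a"] == 1.0
        assert report.per_group_accuracy["b"] == 0.0

    def test_total_is_weighted_mean_and_integer_identity(self):
        y = np.array(["a"] * 12 + ["b"] * 8)
        X = np.zeros((20, 1))
        r = cross_validate(X, y, MajorityClassifier(), n_folds=4, seed=1)
        # Q * sum(N_i) == sum(T_i) exactly
        assert r.total_accuracy * r.n_per_group.sum() == pytest.approx(
            r.correct_per_group.sum(), abs=1e-12
        )
        weighted = (r.per_group_accuracy * r.n_per_group).sum() / r.n_per_group.sum()
        assert r.total_accuracy == pytest.approx(weighted, abs=1e-12)


class TestEvaluateSplit:
    def test_overlapping_indices_rejected(self):
        X = np.zeros((10, 1))
        y = np.array(["a", "b"] * 5)
        with pytest.raises(ValueError, match="overlap"):
            evaluate_split(X, y, np.arange(6), np.arange(4, 10), MajorityClassifier())

    def test_single_correct_test_sample_scores_one(self):
        y = np.array(["a"] * 6 + ["b"] * 4)
        X = np.zeros((10, 1))
        report = evaluate_split(X, y, np.arange(1, 10), np.array([0]), MajorityClassifier())
        assert report.total_accuracy == 1.0

    def test_confusion_rows_sum_to_group_sizes(self):
        y = np.array(["a"] * 8 + ["b"] * 6)
        X = np.arange(14, dtype=float).reshape(-1, 1)
        report = evaluate_split(
            X, y, np.arange(0, 14, 2), np.arange(1, 14, 2), MajorityClassifier()
        )
        for g in report.n_per_group.index:
            assert report.confusion.loc[g].sum() == report.n_per_group[g]


class TestRepeatSplits:
    def test_single_repetition_sd_is_zero(self):
        y = np.array(["a"] * 30 + ["b"] * 30)
        X = np.zeros((60, 1))

        def pipe(X, y, tr, te, seed):
            return 0.5, 0.5, 1

        summary = repeat_splits(X, y, SplitSpec(0.15, 0), pipe, n_reps=1)
        assert summary.cv_sd == 0.0
        assert summary.test_sd == 0.0

    def test_failures_annotated_with_repetition_index(self):
        y = np.array(["a"] * 30 + ["b"] * 30)
        X = np.zeros((60, 1))

        def pipe(X, y, tr, te, seed):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="repetition 0"):
            repeat_splits(X, y, SplitSpec(0.15, 0), pipe, n_reps=2)

    def test_sd_reflects_split_variability_only(self):
        # A deterministic pipeline that depends only on the test indices:
        # identical split seeds would give sd exactly 0.
        y = np.array(["a"] * 30 + ["b"] * 30)
        X = np.zeros((60, 1))

        def pipe(X, y, tr, te, seed):
            return 0.9, float(te.sum() % 7) / 10, len(te)

        s1 = repeat_splits(X, y, SplitSpec(0.15, 3), pipe, n_reps=4)
        s2 = repeat_splits(X, y, SplitSpec(0.15, 3), pipe, n_reps=4)
        np.testing.assert_array_equal(s1.test_accuracies, s2.test_accuracies)
        assert s1.cv_sd == 0.0  # cv accuracy constant across reps


class TestMinorAlleleFrequency:
    def test_all_zero_group_has_frequency_zero(self):
        X = np.zeros((4, 2), dtype=np.int8)
        out = minor_allele_frequency(X, ["a"] * 4)
        assert (out.to_numpy() == 0).all()

    def test_hand_computed_frequency(self):
        X = np.array([[0], [1], [2], [1]], dtype=np.int8)
        out = minor_allele_frequency(X, ["a"] * 4)
        assert out.iloc[0, 0] == pytest.approx(0.5)

    def test_all_missing_group_is_nan(self):
        X = np.array([[MISSING], [MISSING], [1]], dtype=np.int8)
        out = minor_allele_frequency(X, ["a", "a", "b"])
        assert np.isnan(out.loc["a"].iloc[0])
        assert out.loc["b"].iloc[0] == pytest.approx(0.5)

    def test_recovers_simulator_truth_within_binomial_ci(self, small_dataset):
        ds = small_dataset
        out = minor_allele_frequency(ds.genotypes.values, ds.labels, ds.genotypes.rsids)
        truth = ds.freq_table
        n = 40  # samples per group
        se = np.sqrt(truth * (1 - truth) / (2 * n)) + 1e-9
        diff = (out - truth).abs()
        assert (diff.to_numpy() < 5 * se.to_numpy() + 0.01).all()

    def test_major_allele_recode_is_complement(self, small_dataset):
        ds = small_dataset
        vals = ds.genotypes.values
        out = minor_allele_frequency(vals, ds.labels)
        flipped = minor_allele_frequency(2 - vals, ds.labels)
        np.testing.assert_allclose(
            out.to_numpy() + flipped.to_numpy(), 1.0, atol=1e-12
        )
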