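"""Splitting, SVM training, metrics arithmetic and the classification LOD."""

import numpy as np
import pytest

from metaldecoder.features import FeatureMatrix
from metaldecoder.svm_models import (
    NOT_DETECTED,
    ClassMetrics,
    ConfusionMatrix,
    SvmConfig,
    crossvalidate,
    determine_lod_classification,
    evaluate_classifier,
    metrics_from_confusion,
    stratified_split,
    train_svm,
)

from .oracles import confusion_metrics, lod_rule_bruteforce


def _labels_fm(counts: dict, rng=None, dim=4):
    rng = np.random.default_rng(0) if rng is None else rng
    labels = np.concatenate([np.full(n, c) for c, n in sorted(counts.items())])
    return FeatureMatrix(rng.normal(size=(labels.size, dim)), labels)


class TestStratifiedSplit:
    def test_study_layout_counts(self):
        fm = _labels_fm({0: 9600, 1: 1200, 2: 1200})
        train, hold = stratified_split(fm, 0.2, seed=0)
        assert hold.class_counts == {0: 1920, 1: 240, 2: 240}
        assert train.class_counts == {0: 7680, 1: 960, 2: 960}

    def test_partition_is_disjoint_and_complete(self):
        fm = _labels_fm({0: 53, 1: 47})
        train, hold = stratified_split(fm, 0.3, seed=1)
        assert len(train) + len(hold) == len(fm)
        joined = np.sort(np.concatenate([train.scores[:, 0], hold.scores[:, 0]]))
        np.testing.assert_array_equal(joined, np.sort(fm.scores[:, 0]))

    def test_zero_fraction_empty_holdout(self):
        fm = _labels_fm({0: 10, 1: 10})
        train, hold = stratified_split(fm, 0.0, seed=0)
        assert len(hold) == 0 and len(train) == 20

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(_labels_fm({0: 50, 1: 3}), 0.2, seed=0)


class TestTrainSvm:
    def _separable(self, rng):
        scores = np.vstack([rng.normal(0, 0.2, (40, 3)), rng.normal(5, 0.2, (40, 3))])
        return FeatureMatrix(scores, np.repeat([0, 1], 40))

    def test_separable_clusters_perfect_training_accuracy(self, rng):
        fm = self._separable(rng)
        clf = train_svm(fm)
        assert (clf.predict(fm.scores) == fm.labels).all()

    def test_deterministic_decision_function(self, rng):
        fm = self._separable(rng)
        a = train_svm(fm, SvmConfig(seed=3)).decision_function(fm.scores)
        b = train_svm(fm, SvmConfig(seed=3)).decision_function(fm.scores)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(20, 3)), np.zeros(20, int))
        with pytest.raises(ValueError):
            train_svm(fm)


class TestMetrics:
    def test_hand_arithmetic_two_class(self):
        cm = ConfusionMatrix(np.array([0, 1]), np.array([[9, 1], [2, 8]]))
        m = metrics_from_confusion(cm)
        # class 1: TP=8, FN=2, FP=1, TN=9
        assert m.sensitivity[1] == pytest.approx(0.8)
        assert m.specificity[1] == pytest.approx(0.9)
        assert m.accuracy[1] == pytest.approx(0.85)

    def test_perfect_predictions_all_ones(self):
        cm = ConfusionMatrix(np.arange(3), np.diag([5, 7, 9]))
        m = metrics_from_confusion(cm)
        np.testing.assert_allclose(m.sensitivity, 1.0)
        np.testing.assert_allclose(m.specificity, 1.0)
        np.testing.assert_allclose(m.accuracy, 1.0)

    def test_all_one_class_predictor(self):
        cm = ConfusionMatrix(np.array([0, 1]), np.array([[10, 0], [10, 0]]))
        m = metrics_from_confusion(cm)
        assert m.sensitivity[0] == 1.0 and m.specificity[0] == 0.0

    def test_random_tables_match_counting_oracle(self, rng):
        for _ in range(100):
            k = rng.integers(2, 6)
            counts = rng.integers(0, 40, size=(k, k))
            counts += np.eye(k, dtype=int)  # avoid empty rows
            m = metrics_from_confusion(ConfusionMatrix(np.arange(k), counts))
            expected = confusion_metrics(counts)
            np.testing.assert_allclose(m.sensitivity, expected[:, 0], atol=1e-12)
            np.testing.assert_allclose(m.specificity, expected[:, 1], atol=1e-12)
            np.testing.assert_allclose(m.accuracy, expected[:, 2], atol=1e-12)


class TestEvaluateClassifier:
    def test_row_sums_match_holdout_counts(self, rng):
        scores = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (20, 3))])
        fm = FeatureMatrix(scores, np.repeat([0, 1], [30, 20]))
        clf = train_svm(fm)
        cm, _ = evaluate_classifier(clf, fm)
        np.testing.assert_array_equal(cm.row_totals, [30, 20])

    def test_unseen_class_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(40, 3)), np.repeat([0, 1], 20))
        clf = train_svm(fm)
        bad = FeatureMatrix(rng.normal(size=(5, 3)), np.full(5, 7))
        with pytest.raises(ValueError, match="unseen"):
            evaluate_classifier(clf, bad)

    def test_empty_holdout_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(40, 3)), np.repeat([0, 1], 20))
        clf = train_svm(fm)
        with pytest.raises(ValueError):
            evaluate_classifier(clf, fm.subset(np.empty(0, int)))


class TestCrossvalidate:
    def _fm(self, rng):
        scores = np.vstack([rng.normal(0, 1, (80, 3)), rng.normal(4, 1, (40, 3))])
        return FeatureMatrix(scores, np.repeat([0, 1], [80, 40]))

    def test_ten_folds_partition_data(self, rng):
        fm = self._fm(rng)
        records = crossvalidate(fm, n_folds=10)
        assert len(records) == 10
        total = sum(r["confusion"].counts.sum() for r in records)
        assert total == len(fm)

    def test_no_synthetic_rows_in_validation_folds(self, rng):
        fm = self._fm(rng)
        records = crossvalidate(fm, n_folds=5, smote_targets={1: 80})
        assert all(r["n_synthetic_in_val"] == 0 for r in records)

    def test_class_smaller_than_folds_rejected(self, rng):
        fm = FeatureMatrix(rng.normal(size=(12, 3)),
                           np.repeat([0, 1], [9, 3]))
        with pytest.raises(ValueError):
            crossvalidate(fm, n_folds=5)


class TestLodRule:
    CONC = [1e-12, 1e-11, 1e-10, 1e-9]

    def _cm(self, counts):
        return ConfusionMatrix(np.arange(len(counts)), np.array(counts))

    def test_identity_matrix_lod_is_lowest_concentration(self):
        cm = self._cm(np.diag([100] * 5).tolist())
        lod, _ = determine_lod_classification(cm, self.CONC)
        assert lod == self.CONC[0]

    def test_constructed_confusion_pushes_lod_up(self):
        counts = np.diag([100] * 5)
        counts[1, 0], counts[1, 1] = 5, 95  # class 1 leaks 5% into control
        lod, fracs = determine_lod_classification(self._cm(counts.tolist()), self.CONC)
        assert lod == self.CONC[1]
        assert fracs[1] == pytest.approx(0.05)

    def test_all_predicted_control_not_detected(self):
        counts = np.zeros((5, 5), int)
        counts[:, 0] = 100
        lod, _ = determine_lod_classification(self._cm(counts.tolist()), self.CONC)
        assert lod is NOT_DETECTED

    def test_symmetric_rule_gates_control_to_class_direction(self):
        counts = np.diag([100] * 5)
        counts[0, 2], counts[0, 0] = 5, 95  # control leaks into class 2
        lod_sym, _ = determine_lod_classification(self._cm(counts.tolist()), self.CONC)
        lod_row, _ = determine_lod_classification(
            self._cm(counts.tolist()), self.CONC, rule="row"
        )
        assert lod_sym == self.CONC[2]  # symmetric rule pushed past class 2
        assert lod_row == self.CONC[0]  # row-only reading ignores it

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 30, size=(5, 5)) + np.eye(5, dtype=int) * 30
            lod, _ = determine_lod_classification(
                self._cm(counts.tolist()), self.CONC
            )
            assert lod == lod_rule_bruteforce(counts, self.CONC)

    def test_monotone_under_added_confusion(self, rng):
        """Adding class<->control confusion at or above the LOD never lowers it."""
        for _ in range(50):
            counts = rng.integers(0, 2, size=(5, 5)) + np.eye(5, dtype=int) * 100
            cm = self._cm(counts.tolist())
            lod, _ = determine_lod_classification(cm, self.CONC)
            if lod is NOT_DETECTED:
                continue
            j = self.CONC.index(lod) + 1  # row of the LOD class
            worse = counts.copy()
            worse[j, 0] += 10
            lod2, _ = determine_lod_classification(self._cm(worse.tolist()), self.CONC)
            assert lod2 is NOT_DETECTED or lod2 >= lod
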