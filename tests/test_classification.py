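"""Metrics, stratified folds, SMOTE, forest contract and within-subject CV."""

import numpy as np
import pytest
import sklearn.metrics as skm

from gazemind import (
    ConfusionCounts,
    CVConfig,
    auc,
    balanced_accuracy,
    confusion_counts,
    fit_forest,
    kappa,
    mcc,
    run_repeated,
    run_within_subject_cv,
    smote_balance,
    stratified_folds,
)


class TestMetricIdentities:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(10, 10, 0, 0)) == 1.0

    def test_total_inversion(self):
        assert mcc(ConfusionCounts(0, 0, 10, 10)) == -1.0

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(10, 0, 0, 10)) == 0.0  # no negatives at all
        assert mcc(ConfusionCounts(0, 0, 0, 0)) == 0.0

    def test_contingency_example_direct_substitution(self):
        counts = ConfusionCounts(tp=40, tn=30, fp=10, fn=20)
        expected = (40 * 30 - 10 * 20) / np.sqrt(50 * 60 * 40 * 50)
        assert mcc(counts) == pytest.approx(expected)
        assert mcc(counts) == pytest.approx(0.4082, abs=1e-4)

    def test_balanced_accuracy_hand_computation(self):
        counts = ConfusionCounts(tp=40, tn=30, fp=10, fn=20)
        assert balanced_accuracy(counts) == pytest.approx((40 / 60 + 30 / 40) / 2)
        assert balanced_accuracy(counts) == pytest.approx(0.7083, abs=1e-4)

    def test_kappa_hand_computation(self):
        # p_o = 0.7; p_e = (50*60 + 50*40)/100^2 = 0.5 -> kappa = 0.4
        counts = ConfusionCounts(tp=40, tn=30, fp=10, fn=20)
        assert kappa(counts) == pytest.approx(0.4)

    def test_auc_hand_computation_with_tie(self):
        y = [1, 1, 0, 0]
        s = [0.9, 0.5, 0.5, 0.1]
        # pairs: (0.9>0.5), (0.9>0.1), (0.5=0.5 -> 1/2), (0.5>0.1) => 3.5/4
        assert auc(y, s) == pytest.approx(3.5 / 4)

    def test_perfect_and_chance_auc(self, rng):
        y = np.repeat([0, 1], 50)
        assert auc(y, y.astype(float)) == 1.0
        s = rng.random(5000)
        y2 = rng.integers(0, 2, 5000)
        assert auc(y2, s) == pytest.approx(0.5, abs=0.03)

    def test_metrics_match_sklearn_on_random_predictions(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 60)
            p = rng.integers(0, 2, 60)
            s = rng.random(60)
            if len(np.unique(y)) < 2:
                continue
            c = confusion_counts(y, p)
            assert mcc(c) == pytest.approx(skm.matthews_corrcoef(y, p), abs=1e-12)
            assert kappa(c) == pytest.approx(skm.cohen_kappa_score(y, p), abs=1e-12)
            assert balanced_accuracy(c) == pytest.approx(skm.balanced_accuracy_score(y, p), abs=1e-12)
            assert auc(y, s) == pytest.approx(skm.roc_auc_score(y, s), abs=1e-12)

    def test_mcc_and_kappa_symmetric_under_class_swap(self, rng):
        y = rng.integers(0, 2, 80)
        p = rng.integers(0, 2, 80)
        c = confusion_counts(y, p)
        c_swapped = confusion_counts(1 - y, 1 - p)
        assert mcc(c) == pytest.approx(mcc(c_swapped))
        assert kappa(c) == pytest.approx(kappa(c_swapped))

    def test_undefined_when_class_absent(self):
        assert np.isnan(balanced_accuracy(ConfusionCounts(5, 0, 0, 0)))
        assert np.isnan(auc([1, 1], [0.2, 0.4]))


class TestStratifiedFolds:
    def test_exact_divisibility(self, rng):
        y = np.repeat([0, 1], 10)
        folds = stratified_folds(y, 5, rng)
        for fold in folds:
            assert (y[fold] == 0).sum() == 2 and (y[fold] == 1).sum() == 2

    def test_remainder_within_one_and_partition(self, rng):
        y = np.array([1] * 11 + [0] * 10)
        folds = stratified_folds(y, 5, rng)
        all_idx = np.sort(np.concatenate(folds))
        assert np.array_equal(all_idx, np.arange(21))
        pos_counts = [(y[f] == 1).sum() for f in folds]
        assert max(pos_counts) - min(pos_counts) <= 1
        assert sum(pos_counts) == 11

    def test_small_class_rejected(self, rng):
        y = np.array([1] * 4 + [0] * 20)
        with pytest.raises(ValueError, match="stratified"):
            stratified_folds(y, 5, rng)


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(40, 5))
        y = np.repeat([0, 1], 20)
        Xb, yb = smote_balance(X, y, rng=rng)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_minority_raised_to_parity(self, rng):
        X = rng.normal(size=(50, 4))
        y = np.array([1] * 10 + [0] * 40)
        Xb, yb = smote_balance(X, y, rng=rng)
        assert (yb == 1).sum() == 40 and (yb == 0).sum() == 40
        assert len(Xb) == 80

    def test_synthetic_points_on_minority_segments(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 8 + [0] * 22)
        Xb, yb = smote_balance(X, y, k_neighbors=5, rng=rng)
        minority = X[y == 1]
        for point in Xb[len(X):]:
            # collinear with some pair of minority points, between them
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    if np.allclose(d, 0):
                        continue
                    u = np.dot(point - minority[i], d) / np.dot(d, d)
                    if -1e-9 <= u < 1 and np.allclose(minority[i] + u * d, point, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_singleton_minority_duplicated(self, rng):
        X = rng.normal(size=(11, 3))
        y = np.array([1] + [0] * 10)
        Xb, yb = smote_balance(X, y, rng=rng)
        assert (yb == 1).sum() == 10
        assert np.allclose(Xb[11:], X[0])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            smote_balance(rng.normal(size=(10, 2)), np.zeros(10), rng=rng)

    def test_inputs_not_mutated(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 5 + [0] * 25)
        X_copy, y_copy = X.copy(), y.copy()
        smote_balance(X, y, rng=rng)
        assert np.array_equal(X, X_copy) and np.array_equal(y, y_copy)


class TestForest:
    def test_separable_data_perfect_on_train(self, rng):
        X = np.vstack([rng.normal(-5, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        y = np.repeat([0, 1], 20)
        predictor = fit_forest(X, y, n_trees=50, seed=3)
        assert np.array_equal(predictor.predict(X), y)

    def test_same_seed_same_predictions(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60)
        a = fit_forest(X, y, 30, seed=9).score(X)
        b = fit_forest(X, y, 30, seed=9).score(X)
        assert np.array_equal(a, b)

    def test_score_is_tree_vote_fraction(self, rng):
        X = rng.normal(size=(80, 4))
        y = rng.integers(0, 2, 80)
        predictor = fit_forest(X, y, 25, seed=1)
        clf = predictor._clf
        votes = np.stack([clf.classes_[t.predict(X[:10]).astype(int)] for t in clf.estimators_])
        assert np.allclose(predictor.score(X[:10]), (votes == 1).mean(axis=0))
        assert np.all((predictor.score(X[:10]) >= 0) & (predictor.score(X[:10]) <= 1))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_forest(np.empty((0, 3)), np.empty(0), 10, 0)


class TestWithinSubjectCV:
    def test_folds_partition_and_no_leakage(self, rng):
        X = rng.normal(size=(60, 6))
        y = np.repeat([0, 1], 30)
        X_before = X.copy()
        fold_metrics, fold_mean = run_within_subject_cv(X, y, CVConfig(n_iterations=1, seed=4))
        assert len(fold_metrics) == 5
        # test rows bit-identical after the run (SMOTE never touched them)
        assert np.array_equal(X, X_before)
        for m in fold_metrics:
            assert -1 <= m.mcc <= 1 and 0 <= m.auc <= 1

    def test_separable_participant_near_perfect(self, rng):
        X = np.vstack([rng.normal(-4, 0.2, (25, 4)), rng.normal(4, 0.2, (25, 4))])
        y = np.repeat([0, 1], 25)
        _, fold_mean = run_within_subject_cv(X, y, CVConfig(seed=2))
        assert fold_mean.mcc > 0.95 and fold_mean.auc > 0.99

    def test_null_participant_near_chance(self, rng):
        values = []
        for seed in range(8):
            X = rng.normal(size=(80, 6))
            y = np.repeat([0, 1], 40)
            _, fold_mean = run_within_subject_cv(X, y, CVConfig(seed=seed))
            values.append(fold_mean.mcc)
        assert abs(np.mean(values)) < 0.12

    def test_determinism_same_seed(self, rng):
        X = rng.normal(size=(50, 5))
        y = np.repeat([0, 1], 25)
        _, a = run_within_subject_cv(X, y, CVConfig(seed=11))
        _, b = run_within_subject_cv(X, y, CVConfig(seed=11))
        assert a == b


class TestRunRepeated:
    def cohort(self, rng, n=40, separable=False):
        out = {}
        for p in range(2):
            if separable:
                X = np.vstack([rng.normal(-4, 0.2, (n // 2, 4)), rng.normal(4, 0.2, (n // 2, 4))])
            else:
                X = rng.normal(size=(n, 4))
            y = np.repeat([0, 1], n // 2)
            out[f"p{p}"] = (X, y)
        return out

    def test_single_iteration_degenerate_aggregation(self, rng):
        result = run_repeated(self.cohort(rng), CVConfig(n_iterations=1, seed=5))
        assert (result.summary["mean"] == result.summary["max"]).all()
        assert (result.summary["mean"] == result.summary["min"]).all()

    def test_min_le_mean_le_max(self, rng):
        result = run_repeated(self.cohort(rng), CVConfig(n_iterations=5, seed=5))
        assert (result.summary["min"] <= result.summary["mean"] + 1e-12).all()
        assert (result.summary["mean"] <= result.summary["max"] + 1e-12).all()

    def test_feature_mask_restricts_columns(self, rng):
        cohort = self.cohort(rng, separable=True)
        full = run_repeated(cohort, CVConfig(n_iterations=1, seed=7))
        masked = run_repeated(cohort, CVConfig(n_iterations=1, seed=7), feature_mask=[0, 1])
        assert masked.summary.loc["mcc", "mean"] > 0.9
        assert full.n_participants == masked.n_participants == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="participant"):
            run_repeated({}, CVConfig(n_iterations=1))
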