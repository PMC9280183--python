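"""Softmax/cross-entropy closed forms, RMSprop training contracts, K-fold metrics."""

import copy

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from eegfusion.classifier import (
    ClassifierConfig,
    ClassifierError,
    SoftmaxImageClassifier,
    cross_entropy,
    kfold_evaluate,
    softmax,
    train,
)


class TestSoftmax:
    def test_symmetric_scores_give_uniform_probabilities(self):
        assert np.allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5], atol=0)

    def test_shift_invariance(self, rng):
        scores = rng.normal(size=7)
        assert np.allclose(softmax(scores), softmax(scores + 123.456), atol=1e-12)

    def test_log_integer_scores_give_rational_probabilities(self):
        p = softmax(np.log(np.array([1.0, 2.0, 3.0])))
        assert np.allclose(p, [1 / 6, 2 / 6, 3 / 6], atol=1e-12)

    def test_output_lies_in_simplex_for_random_batches(self, rng):
        scores = rng.normal(scale=50, size=(10_000, 5))
        p = softmax(scores)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ClassifierError):
            softmax(np.array([np.inf, 0.0]))


class TestCrossEntropy:
    def test_perfect_binary_prediction_is_zero_loss(self):
        assert cross_entropy(np.array([1.0]), np.array([1.0])) == pytest.approx(0.0, abs=1e-10)

    def test_binary_half_probability_is_ln_two(self):
        assert cross_entropy(np.array([1.0]), np.array([0.5])) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_categorical_matches_hand_evaluation(self):
        y = np.array([[0.0, 1.0, 0.0]])
        p = np.array([[0.2, 0.5, 0.3]])
        assert cross_entropy(y, p, binary=False) == pytest.approx(-np.log(0.5), abs=1e-12)

    def test_nonnegative_with_equality_only_at_match(self, rng):
        for _ in range(20):
            scores = rng.normal(size=4)
            p = softmax(scores)[None, :]
            y = np.eye(4)[rng.integers(0, 4)][None, :]
            loss = cross_entropy(y, p, binary=False)
            assert loss >= 0
            assert loss > 1e-6  # softmax of finite scores never hits a vertex

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ClassifierError, match="shape"):
            cross_entropy(np.ones(3), np.ones(4))


def separable_toy(rng, n=40, d=30, gap=3.0):
    X = rng.normal(size=(n, d))
    y = np.array([0, 1] * (n // 2))
    X[y == 1, 0] += gap
    return X, y


class TestTraining:
    def test_zero_epochs_returns_initial_parameters(self, rng):
        X, y = separable_toy(rng)
        cfg = ClassifierConfig(epochs=0, seed=3)
        reference = SoftmaxImageClassifier(X.shape[1], cfg)
        model, history = train(X, y, cfg)
        for got, init in zip(model.parameters, reference.parameters):
            assert np.array_equal(got, init)
        assert history["train_loss"] == []

    def test_loss_strictly_decreases_on_separable_data(self, rng):
        X, y = separable_toy(rng)
        cfg = ClassifierConfig(epochs=5, seed=0, dropout_rate=0.0)
        _, history = train(X, y, cfg)
        losses = history["train_loss"]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_same_seed_gives_bitwise_identical_trajectories(self, rng):
        X, y = separable_toy(rng)
        cfg = ClassifierConfig(epochs=4, seed=11)
        m1, h1 = train(X.copy(), y.copy(), cfg)
        m2, h2 = train(X.copy(), y.copy(), cfg)
        assert h1["train_loss"] == h2["train_loss"]
        for a, b in zip(m1.parameters, m2.parameters):
            assert np.array_equal(a, b)

    def test_rmsprop_accumulator_follows_update_rule(self):
        # one step on a single parameterized example, checked by hand
        cfg = ClassifierConfig(epochs=1, seed=0, dropout_rate=0.0, hidden=2)
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        model = SoftmaxImageClassifier(2, cfg)
        before = copy.deepcopy(model.parameters)
        model._step(X, y)
        gamma, lr, eps = cfg.rmsprop_decay, cfg.learning_rate, cfg.rmsprop_eps
        for prev, now, s in zip(before, model.parameters, model._s):
            g2 = s / (1 - gamma)  # first step: s = (1-gamma) g^2
            step = lr * np.sqrt(g2) / np.sqrt(s + eps)
            assert np.all(np.abs(now - prev) <= step + 1e-15)

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ClassifierError, match="single class"):
            train(X, np.zeros(10, dtype=int), ClassifierConfig(epochs=1))


def pair_counting_auc(y, scores):
    """Brute-force Wilcoxon AUC: fraction of (pos, neg) pairs ranked correctly."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_sklearn_auc_equals_pair_counting_oracle(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]  # both classes present
        scores = np.round(rng.normal(size=200), 2)  # ties included
        assert roc_auc_score(y, scores) == pytest.approx(
            pair_counting_auc(y, scores), abs=1e-12
        )

    def test_constant_predictor_on_balanced_set_scores_at_chance(self):
        from eegfusion.classifier import _fold_metrics

        y = np.array([0] * 10 + [1] * 10)
        proba = np.tile([0.9, 0.1], (20, 1))  # always predicts class 0
        acc, _, _, auc = _fold_metrics(y, proba, 2)
        assert acc == pytest.approx(0.5)
        assert auc == pytest.approx(0.5)

    def test_perfect_predictor_scores_one_everywhere(self):
        from eegfusion.classifier import _fold_metrics

        y = np.array([0, 1, 0, 1, 1, 0])
        proba = np.eye(2)[y] * 0.98 + 0.01
        acc, rec, f1, auc = _fold_metrics(y, proba, 2)
        assert (acc, rec, f1, auc) == (1.0, 1.0, 1.0, 1.0)

    def test_accuracy_equals_mean_per_sample_correctness(self, rng):
        from sklearn.metrics import confusion_matrix

        y = rng.integers(0, 3, 60)
        pred = rng.integers(0, 3, 60)
        cm = confusion_matrix(y, pred)
        assert np.trace(cm) / cm.sum() == pytest.approx(np.mean(y == pred))


class TestKFold:
    def test_every_subject_lands_in_exactly_one_fold(self, rng):
        X, y = separable_toy(rng, n=100, d=10)
        report = kfold_evaluate(X, y, ClassifierConfig(epochs=2, seed=0), K=5)
        folds = np.array(report.fold_assignments)
        assert folds.shape == (100,)
        assert set(folds) == set(range(5))
        assert np.bincount(folds).tolist() == [20] * 5

    def test_rates_are_valid_and_curves_recorded(self, rng):
        X, y = separable_toy(rng, n=40, d=10)
        report = kfold_evaluate(X, y, ClassifierConfig(epochs=3, seed=1), K=5)
        for rates in (report.fold_accuracy, report.fold_recall, report.fold_f1, report.fold_auc):
            assert all(0 <= r <= 1 for r in rates)
        assert len(report.val_accuracy_curves) == 5
        assert all(len(c) == 3 for c in report.val_accuracy_curves)

    def test_underfilled_class_fails_stratification(self, rng):
        X = rng.normal(size=(20, 5))
        y = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ClassifierError, match="stratified"):
            kfold_evaluate(X, y, ClassifierConfig(epochs=1), K=5)
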