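"""Classification head and evaluation protocol for fused multispectral images.

The model is a compact trainable head: flatten 40x40x3 -> dense(64, ReLU)
-> dropout(0.1) -> dense(e) -> softmax. Training minimizes cross-entropy
(the binary form for two classes, the categorical form otherwise) with the
RMSprop update

    s <- gamma * s + (1 - gamma) * g^2
    theta <- theta - lr * g / sqrt(s + eps)

at learning rate 1e-4. Evaluation uses stratified K=5 cross-validation and
reports per-fold accuracy, recall, F1 and AUC (macro one-vs-rest beyond two
classes), mean validation loss, and per-epoch validation curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClassifierConfig",
    "EvaluationReport",
    "ClassifierError",
    "SoftmaxImageClassifier",
    "softmax",
    "cross_entropy",
    "train",
    "kfold_evaluate",
]


class ClassifierError(ValueError):
    """Raised for invalid training or evaluation input."""


@dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int = 2
    learning_rate: float = 1e-4
    dropout_rate: float = 0.1
    batch_size: int = 64
    epochs: int = 400
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8
    hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ClassifierError("need at least two classes")
        if not 0 <= self.dropout_rate < 1:
            raise ClassifierError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ClassifierError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ClassifierError("invalid batch_size or epochs")


@dataclass
class EvaluationReport:
    """Per-fold and averaged metrics from stratified cross-validation."""

    fold_accuracy: list[float]
    fold_recall: list[float]
    fold_f1: list[float]
    fold_auc: list[float]
    fold_val_loss: list[float]
    mean_accuracy: float
    mean_recall: float
    mean_f1: float
    mean_auc: float
    mean_val_loss: float
    fold_assignments: list[int]
    val_accuracy_curves: list[list[float]] = field(default_factory=list)
    val_loss_curves: list[list[float]] = field(default_factory=list)
    seed: int = 0
    classes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True, indent=1) + "\n")


# --- core functions --------------------------------------------------------

def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalized exponentials exp(F_j) / sum_k exp(F_k), max-shifted for stability."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ClassifierError("softmax requires finite scores")
    shifted = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(y: np.ndarray, p: np.ndarray, *, binary: bool | None = None) -> float:
    """Cross-entropy loss; mean over a batch.

    Binary form -(y log p + (1-y) log(1-p)) when ``y``/``p`` are scalar
    probabilities of the positive class; categorical form
    -sum_c y_c log p_c when they are one-hot rows and probability rows.
    Probabilities are clamped at 1e-12 away from {0, 1}.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if y.shape != p.shape:
        raise ClassifierError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    if binary is None:
        binary = y.ndim == 1
    if binary:
        losses = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        return float(np.mean(losses))
    losses = -np.sum(y * np.log(p), axis=-1)
    return float(np.mean(losses))


# --- model -----------------------------------------------------------------

class SoftmaxImageClassifier:
    """Flatten -> dense(hidden, ReLU) -> dropout -> dense(e) -> softmax.

    Inputs are centered on the training-set per-feature mean before the
    first layer (mean-intensity subtraction, as is standard for image
    classification heads; raw pixels are all-positive, which cripples
    first-layer gradient directions). Parameters are He-initialized from
    the config seed; training is deterministic for a fixed seed (shuffling
    and dropout masks come from one seeded generator).
    """

    def __init__(self, n_features: int, cfg: ClassifierConfig):
        self.cfg = cfg
        self.n_features = n_features
        self.feature_mean = np.zeros(n_features)
        rng = np.random.default_rng(cfg.seed)
        h, e = cfg.hidden, cfg.n_classes
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / n_features), (n_features, h))
        self.b1 = np.zeros(h)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / h), (h, e))
        self.b2 = np.zeros(e)
        self._rng = rng
        # RMSprop accumulators, one per parameter tensor
        self._s = [np.zeros_like(p) for p in (self.W1, self.b1, self.W2, self.b2)]

    @property
    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2]

    def _forward(self, X: np.ndarray, *, training: bool = False):
        z1 = (X - self.feature_mean) @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0)
        mask = None
        if training and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (self._rng.random(a1.shape) < keep) / keep
            a1 = a1 * mask
        scores = a1 @ self.W2 + self.b2
        return z1, a1, mask, softmax(scores)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).reshape(len(X), -1)
        return self._forward(X)[3]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        onehot = np.eye(self.cfg.n_classes)[np.asarray(y, dtype=int)]
        if self.cfg.n_classes == 2:
            return cross_entropy(onehot[:, 1], p[:, 1])
        return cross_entropy(onehot, p, binary=False)

    def _step(self, X: np.ndarray, y: np.ndarray) -> None:
        n = len(X)
        z1, a1, mask, p = self._forward(X, training=True)
        onehot = np.eye(self.cfg.n_classes)[y]
        dscores = (p - onehot) / n  # gradient of mean cross-entropy wrt scores
        gW2 = a1.T @ dscores
        gb2 = dscores.sum(axis=0)
        da1 = dscores @ self.W2.T
        if mask is not None:
            da1 = da1 * mask
        dz1 = da1 * (z1 > 0)
        gW1 = (X - self.feature_mean).T @ dz1
        gb1 = dz1.sum(axis=0)
        gamma, lr, eps = self.cfg.rmsprop_decay, self.cfg.learning_rate, self.cfg.rmsprop_eps
        for param, grad, s in zip(self.parameters, (gW1, gb1, gW2, gb2), self._s):
            s *= gamma
            s += (1.0 - gamma) * grad**2
            param -= lr * grad / np.sqrt(s + eps)


def train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ClassifierConfig,
    *,
    model: SoftmaxImageClassifier | None = None,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[SoftmaxImageClassifier, dict[str, list[float]]]:
    """Fit the head by mini-batch RMSprop; returns (model, history).

    ``history`` holds per-epoch training loss and, when a validation set is
    supplied, validation loss and accuracy curves. Zero epochs returns the
    freshly initialized model untouched.
    """
    X = np.asarray(X, dtype=float).reshape(len(X), -1)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ClassifierError("training set contains a single class")
    if classes.max() >= cfg.n_classes:
        raise ClassifierError("label exceeds configured number of classes")
    if model is None:
        model = SoftmaxImageClassifier(X.shape[1], cfg)
        model.feature_mean = X.mean(axis=0)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    has_val = X_val is not None and y_val is not None
    if has_val:
        X_val = np.asarray(X_val, dtype=float).reshape(len(X_val), -1)
        y_val = np.asarray(y_val, dtype=int)
    rng = model._rng
    n = len(X)
    bs = min(cfg.batch_size, n)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            model._step(X[idx], y[idx])
        history["train_loss"].append(model.loss(X, y))
        if has_val:
            history["val_loss"].append(model.loss(X_val, y_val))
            history["val_accuracy"].append(float(np.mean(model.predict(X_val) == y_val)))
    return model, history


# --- evaluation protocol ---------------------------------------------------

def _fold_metrics(y_true: np.ndarray, proba: np.ndarray, n_classes: int):
    y_pred = proba.argmax(axis=1)
    acc = accuracy_score(y_true, y_pred)
    if n_classes == 2:
        rec = recall_score(y_true, y_pred, zero_division=0)
        f1 = f1_score(y_true, y_pred, zero_division=0)
        auc = roc_auc_score(y_true, proba[:, 1])
    else:
        rec = recall_score(y_true, y_pred, average="macro", zero_division=0)
        f1 = f1_score(y_true, y_pred, average="macro", zero_division=0)
        auc = roc_auc_score(y_true, proba, multi_class="ovr", average="macro")
    return float(acc), float(rec), float(f1), float(auc)


def kfold_evaluate(
    X: np.ndarray,
    y: Sequence,
    cfg: ClassifierConfig | None = None,
    K: int = 5,
) -> EvaluationReport:
    """Stratified K-fold evaluation of the softmax head on image data.

    ``y`` may hold arbitrary class tags; they are mapped to indices in
    sorted order. Every subject lands in exactly one validation fold.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float).reshape(len(X), -1)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != cfg.n_classes:
        cfg = ClassifierConfig(**{**asdict(cfg), "n_classes": len(classes)})
    y_idx = np.searchsorted(classes, y)
    if len(X) < K:
        raise ClassifierError(f"need at least K={K} subjects, got {len(X)}")
    counts = np.bincount(y_idx)
    if counts.min() < K:
        raise ClassifierError(
            "stratified folds infeasible: a class has fewer members than K"
        )

    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=cfg.seed)
    assignments = np.full(len(X), -1, dtype=int)
    accs, recs, f1s, aucs, losses = [], [], [], [], []
    acc_curves, loss_curves = [], []
    for fold, (tr, va) in enumerate(skf.split(X, y_idx)):
        assignments[va] = fold
        fold_cfg = ClassifierConfig(**{**asdict(cfg), "seed": cfg.seed + fold})
        model, hist = train(X[tr], y_idx[tr], fold_cfg, X_val=X[va], y_val=y_idx[va])
        proba = model.predict_proba(X[va])
        a, r, f, u = _fold_metrics(y_idx[va], proba, fold_cfg.n_classes)
        accs.append(a), recs.append(r), f1s.append(f), aucs.append(u)
        losses.append(model.loss(X[va], y_idx[va]))
        acc_curves.append(hist["val_accuracy"])
        loss_curves.append(hist["val_loss"])

    return EvaluationReport(
        fold_accuracy=accs,
        fold_recall=recs,
        fold_f1=f1s,
        fold_auc=aucs,
        fold_val_loss=losses,
        mean_accuracy=float(np.mean(accs)),
        mean_recall=float(np.mean(recs)),
        mean_f1=float(np.mean(f1s)),
        mean_auc=float(np.mean(aucs)),
        mean_val_loss=float(np.mean(losses)),
        fold_assignments=assignments.tolist(),
        val_accuracy_curves=acc_curves,
        val_loss_curves=loss_curves,
        seed=cfg.seed,
        classes=[str(c) for c in classes],
    )
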