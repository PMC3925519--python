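"""Linear classification of feature vectors, and confusion-matrix metrics.

The decision rule is the classical linear one: each class k carries a weight
vector w_k (with bias), the score of input x is w_k . x + b_k, and the
predicted label is the argmax (ties broken toward the lowest class index).

Two trainers produce the weights:

``"lda"`` (default)
    Pooled-covariance linear discriminant analysis — the classical "linear
    classifier": w_k = Sigma^-1 mu_k, b_k = -mu_k.w_k / 2 + ln(pi_k), where
    Sigma is the within-class scatter pooled over classes with an N - K
    denominator and pi_k are the empirical class priors.  A singular scatter
    triggers a ridge-regularised solve (Sigma + eps*tr(Sigma)/d * I) with a
    warning.

``"lsq"``
    Least squares onto one-hot class indicators; also linear in the same
    sense, kept for comparison.

Optional z-scoring (train-set mean/std stored in the model) is off by
default.  Models serialize to a documented JSON layout and predict purely
from the stored weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LinearModel",
    "ConfusionMatrix",
    "train",
    "predict",
    "confusion",
    "metrics_from_confusion",
]

_RIDGE_EPS = 1e-8


@dataclass
class ConfusionMatrix:
    """Integer count matrix, rows = true class, columns = predicted class."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, label) -> np.ndarray:
        return self.counts[self.labels.index(label)]


@dataclass
class LinearModel:
    """Per-class linear discriminants with an argmax decision rule.

    ``weights`` has shape (n_classes, n_features + 1); the final column is the
    bias.  Prediction is a pure function of the stored weights, so a model
    round-trips through JSON with bit-identical behaviour.
    """

    class_labels: tuple
    weights: np.ndarray
    feature_names: tuple[str, ...]
    trainer: str = "lda"
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (len(self.class_labels), len(self.feature_names) + 1):
            raise ValueError(
                f"weights must be ({len(self.class_labels)}, "
                f"{len(self.feature_names) + 1}), got {self.weights.shape}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Discriminant scores, shape (n_samples, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, received {X.shape[1]}"
            )
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_std
        return X @ self.weights[:, :-1].T + self.weights[:, -1]

    def predict(self, X: np.ndarray):
        """Predicted labels; a 1-D input returns a scalar label.

        Ties take the lowest class index (np.argmax's first-maximum rule).
        """
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        idx = np.argmax(self.scores(X), axis=1)
        labels = [self.class_labels[i] for i in idx]
        return labels[0] if single else np.asarray(labels)

    def to_json(self) -> str:
        payload = {
            "format": "ictal-linear-model-v1",
            "class_labels": list(self.class_labels),
            "feature_names": list(self.feature_names),
            "trainer": self.trainer,
            "weights": self.weights.tolist(),
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_std": None if self.scaler_std is None else self.scaler_std.tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        if d.get("format") != "ictal-linear-model-v1":
            raise ValueError("not a recognised linear-model JSON document")
        return cls(
            class_labels=tuple(d["class_labels"]),
            weights=np.asarray(d["weights"]),
            feature_names=tuple(d["feature_names"]),
            trainer=d["trainer"],
            scaler_mean=None if d["scaler_mean"] is None else np.asarray(d["scaler_mean"]),
            scaler_std=None if d["scaler_std"] is None else np.asarray(d["scaler_std"]),
        )


def _lda_weights(X: np.ndarray, y: np.ndarray, labels: Sequence) -> np.ndarray:
    n, d = X.shape
    k = len(labels)
    means = np.stack([X[y == lab].mean(axis=0) for lab in labels])
    priors = np.array([(y == lab).sum() / n for lab in labels])
    scatter = np.zeros((d, d))
    for lab, mu in zip(labels, means):
        diff = X[y == lab] - mu
        scatter += diff.T @ diff
    cov = scatter / max(n - k, 1)
    try:
        w = np.linalg.solve(cov, means.T).T
        resid = np.linalg.norm(cov @ w.T - means.T)
        if not np.all(np.isfinite(w)) or resid > 1e-6 * max(np.linalg.norm(means), 1e-30):
            raise np.linalg.LinAlgError("unreliable pooled-covariance solve")
    except np.linalg.LinAlgError:
        warnings.warn(
            "singular pooled covariance; falling back to ridge-regularised solve",
            stacklevel=3,
        )
        ridge = _RIDGE_EPS * max(np.trace(cov) / d, 1.0)
        w = np.linalg.solve(cov + ridge * np.eye(d), means.T).T
    bias = -0.5 * np.einsum("kd,kd->k", w, means) + np.log(priors)
    return np.hstack([w, bias[:, None]])


def _lsq_weights(X: np.ndarray, y: np.ndarray, labels: Sequence) -> np.ndarray:
    n = X.shape[0]
    Xb = np.hstack([X, np.ones((n, 1))])
    Y = np.stack([(y == lab).astype(float) for lab in labels], axis=1)
    w, *_ = np.linalg.lstsq(Xb, Y, rcond=None)
    return w.T


def train(
    features: np.ndarray,
    labels: Sequence,
    trainer: str = "lda",
    feature_names: Sequence[str] | None = None,
    standardize: bool = False,
) -> LinearModel:
    """Fit a linear model from labelled feature vectors.

    Requires at least two classes and two samples per class, and finite
    features throughout.  Class labels are ordered by first-seen-sorted order
    (``sorted(set(labels))``) so the tie-break rule is reproducible.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training data")
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    for lab in classes:
        if (y == lab).sum() < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 training samples")
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    scaler_mean = scaler_std = None
    if standardize:
        scaler_mean = X.mean(axis=0)
        scaler_std = X.std(axis=0, ddof=1)
        scaler_std = np.where(scaler_std > 0, scaler_std, 1.0)
        X = (X - scaler_mean) / scaler_std
    if trainer == "lda":
        weights = _lda_weights(X, y, classes)
    elif trainer == "lsq":
        weights = _lsq_weights(X, y, classes)
    else:
        raise ValueError(f"unknown trainer {trainer!r}; use 'lda' or 'lsq'")
    return LinearModel(
        class_labels=classes,
        weights=weights,
        feature_names=tuple(feature_names),
        trainer=trainer,
        scaler_mean=scaler_mean,
        scaler_std=scaler_std,
    )


def predict(model: LinearModel, x: np.ndarray):
    """Label of the maximal discriminant score (see :meth:`LinearModel.predict`)."""
    return model.predict(x)


def confusion(model: LinearModel, test_features: np.ndarray, test_labels) -> ConfusionMatrix:
    """Confusion counts of ``model`` on a labelled test set.

    Rows follow the model's class order; a true label outside that order is an
    error rather than a silently dropped row.
    """
    y_true = np.asarray(test_labels)
    unknown = set(y_true.tolist()) - set(model.class_labels)
    if unknown:
        raise ValueError(f"test labels {sorted(unknown)!r} unseen during training")
    y_pred = model.predict(np.atleast_2d(test_features))
    k = len(model.class_labels)
    counts = np.zeros((k, k), dtype=np.int64)
    index = {lab: i for i, lab in enumerate(model.class_labels)}
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=tuple(model.class_labels), counts=counts)


def metrics_from_confusion(cm: ConfusionMatrix, negative_class) -> dict:
    """Specificity, per-class sensitivities and overall accuracy, in percent.

    Specificity is the correct-rejection rate of the designated negative
    class (its diagonal cell over its row total); sensitivity of each other
    class is its diagonal cell over its row total; accuracy is the trace over
    the grand total.
    """
    if negative_class not in cm.labels:
        raise ValueError(f"negative class {negative_class!r} not among {cm.labels}")
    row_sums = cm.counts.sum(axis=1)
    if (row_sums == 0).any():
        bad = [lab for lab, s in zip(cm.labels, row_sums) if s == 0]
        raise ValueError(f"empty confusion rows for classes {bad!r}")
    diag = np.diag(cm.counts)
    neg = cm.labels.index(negative_class)
    sensitivities = {
        lab: 100.0 * diag[i] / row_sums[i]
        for i, lab in enumerate(cm.labels)
        if i != neg
    }
    return {
        "specificity": 100.0 * diag[neg] / row_sums[neg],
        "sensitivity": sensitivities,
        "accuracy": 100.0 * diag.sum() / cm.total,
    }
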