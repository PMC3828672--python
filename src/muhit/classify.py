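"""Quadratic discriminant classification of hit vs no-hit trials.

QDA models each class as a multivariate Gaussian with its own mean and
covariance; a point is assigned to the class maximizing

    log prior_k - 1/2 log det(Sigma_k) - 1/2 (x - mu_k)' Sigma_k^-1 (x - mu_k).

Covariances are maximum-likelihood estimates with a small ridge
(Sigma + eps * trace(Sigma)/d * I) so that low-count sessions with
degenerate spike-count columns still yield a positive-definite model.
Performance is measured by stratified five-fold cross-validation (80/20
train/test) with the confusion-matrix conventions: a hit is the positive
class, the fold error is (FN + FP) / fold size, the session error is the
mean over folds, accuracy is 100 minus that, and sensitivity/specificity
are TP/(TP+FN) and TN/(TN+FP) on the pooled fold counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "QdaModel",
    "FoldCounts",
    "EvalResult",
    "fit_qda",
    "predict_qda",
    "crossval_5fold",
]


@dataclass
class QdaModel:
    """Per-class Gaussian parameters.  Classes are stored sorted by label
    with ties at prediction broken toward the larger prior, then the
    earlier label."""

    classes: np.ndarray
    means: np.ndarray            # (k, d)
    covariances: np.ndarray      # (k, d, d), ridge-regularized
    priors: np.ndarray           # (k,), empirical, sums to 1
    regularization: float


def fit_qda(X: np.ndarray, y: np.ndarray,
            regularization: float = 1e-6) -> QdaModel:
    """Maximum-likelihood QDA fit with ridge-regularized covariances.

    Requires every class present with >= 2 samples.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit a discriminant")
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples")
    d = X.shape[1]
    means = np.empty((len(classes), d))
    covs = np.empty((len(classes), d, d))
    for k, c in enumerate(classes):
        Xk = X[y == c]
        means[k] = Xk.mean(axis=0)
        S = np.cov(Xk, rowvar=False, bias=True).reshape(d, d)
        ridge = regularization * (np.trace(S) / d) * np.eye(d)
        if np.trace(S) == 0.0:          # fully degenerate class
            ridge = regularization * np.eye(d)
        covs[k] = S + ridge
    priors = counts / counts.sum()
    return QdaModel(classes=classes, means=means, covariances=covs,
                    priors=priors, regularization=regularization)


def _log_posteriors(model: QdaModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior per class, shape (n, k)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"dimension {model.means.shape[1]}"
        )
    n, k = X.shape[0], len(model.classes)
    scores = np.empty((n, k))
    for j in range(k):
        diff = X - model.means[j]
        sign, logdet = np.linalg.slogdet(model.covariances[j])
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance not positive definite")
        sol = np.linalg.solve(model.covariances[j], diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        scores[:, j] = np.log(model.priors[j]) - 0.5 * logdet - 0.5 * maha
    return scores


def predict_qda(model: QdaModel, X: np.ndarray) -> np.ndarray:
    """Bayes-rule class assignment; deterministic.

    Exact posterior ties go to the class with the larger prior, then to the
    earlier label in sorted order.
    """
    scores = _log_posteriors(model, X)
    # scan classes in (descending prior, ascending label) order so that
    # argmax's first-occurrence rule implements the documented tie-break
    order = np.lexsort((np.arange(len(model.classes)), -model.priors))
    best = order[np.argmax(scores[:, order], axis=1)]
    return model.classes[best]


@dataclass(frozen=True)
class FoldCounts:
    """Confusion counts of one CV fold (hit = positive class)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def error_pct(self) -> float:
        return 100.0 * (self.fn + self.fp) / self.n


@dataclass
class EvalResult:
    """Cross-validated confusion counts and the derived percentages."""

    folds: list[FoldCounts]
    seed: int = 0

    @property
    def per_fold_error_pct(self) -> np.ndarray:
        return np.array([f.error_pct for f in self.folds])

    @property
    def mean_error_pct(self) -> float:
        return float(self.per_fold_error_pct.mean())

    @property
    def accuracy_pct(self) -> float:
        return 100.0 - self.mean_error_pct

    def _pooled(self) -> FoldCounts:
        return FoldCounts(
            tp=sum(f.tp for f in self.folds),
            fn=sum(f.fn for f in self.folds),
            tn=sum(f.tn for f in self.folds),
            fp=sum(f.fp for f in self.folds),
        )

    @property
    def sensitivity_pct(self) -> float:
        p = self._pooled()
        return 100.0 * p.tp / (p.tp + p.fn)

    @property
    def specificity_pct(self) -> float:
        p = self._pooled()
        return 100.0 * p.tn / (p.tn + p.fp)

    def to_dict(self) -> dict:
        return {
            "per_fold": [
                {"tp": f.tp, "fn": f.fn, "tn": f.tn, "fp": f.fp,
                 "error_pct": f.error_pct}
                for f in self.folds
            ],
            "mean_error_pct": self.mean_error_pct,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "seed": self.seed,
        }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     positive=1) -> FoldCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    return FoldCounts(
        tp=int(np.sum(pos & (y_pred == positive))),
        fn=int(np.sum(pos & (y_pred != positive))),
        tn=int(np.sum(~pos & (y_pred != positive))),
        fp=int(np.sum(~pos & (y_pred == positive))),
    )


def crossval_5fold(X: np.ndarray, y: np.ndarray, seed: int = 0,
                   regularization: float = 1e-6,
                   positive=1) -> EvalResult:
    """Seeded, stratified five-fold cross-validation of the QDA decoder.

    Requires at least 5 samples per class so every fold holds both classes.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < 5):
        raise ValueError("need at least 5 samples per class for 5 folds")
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(X, y):
        model = fit_qda(X[train_idx], y[train_idx],
                        regularization=regularization)
        pred = predict_qda(model, X[test_idx])
        folds.append(confusion_counts(y[test_idx], pred, positive=positive))
    return EvalResult(folds=folds, seed=seed)
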