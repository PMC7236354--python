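"""Impairment classification: features, softmax regression, LOOCV and ROC.

The engine maps each subject's test output — the summary score plus the
within-session accuracy and speed trends — together with age, gender and
education into a multinomial (softmax) logistic regression.  Two cognitive
statuses are used here, but the softmax formulation generalizes to more.
Evaluation is by leave-one-out cross-validation: every subject is scored by a
model fitted on all other subjects, with feature standardization re-estimated
inside each training fold so no information leaks from the held-out subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .scoring import SessionResult

FEATURE_NAMES = ("ica_score", "accuracy_trend", "speed_trend", "age", "gender", "education")
CLASSES = ("cognitively_normal", "cognitively_impaired")


class ClassifierError(ValueError):
    """Invalid input to a classifier operation."""


def extract_features(result: SessionResult, age: float, gender: int,
                     education: float) -> np.ndarray:
    """Fixed-order feature vector for one subject.

    Refuses sessions flagged invalid by the scorer (too many outlier trials):
    their summary score is not trustworthy.
    """
    if not result.valid:
        raise ClassifierError("session result is flagged invalid; cannot extract features")
    if gender not in (0, 1):
        raise ClassifierError("gender must be encoded as 0/1")
    vec = np.array(
        [result.ica_score, result.accuracy_trend, result.speed_trend,
         float(age), float(gender), float(education)]
    )
    if not np.all(np.isfinite(vec)):
        raise ClassifierError("non-finite feature value")
    return vec


@dataclass
class ClassifierModel:
    """Fitted softmax regression with per-feature training standardization.

    ``weights`` has shape (n_classes - 1, n_features + 1): rows are the
    non-reference classes, the last column is the intercept; the reference
    class (index 0) is pinned at zero.
    """

    weights: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    reg_lambda: float
    classes: tuple[str, ...] = CLASSES
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    @property
    def n_features(self) -> int:
        return self.scaler_mean.size

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_sd

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "format_version": 1,
            "weights": self.weights.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "reg_lambda": self.reg_lambda,
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
            scaler_sd=np.asarray(d["scaler_sd"], dtype=float),
            reg_lambda=float(d["reg_lambda"]),
            classes=tuple(d["classes"]),
            feature_names=tuple(d["feature_names"]),
        )


def _softmax_probs(Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Class probabilities with the reference class pinned at logit 0.

    Z: (n, d) standardized features; W: (K-1, d+1). Returns (n, K).
    """
    logits = np.zeros((Z.shape[0], W.shape[0] + 1))
    logits[:, 1:] = Z @ W[:, :-1].T + W[:, -1]
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def fit_mlr(X: np.ndarray, y: Sequence[int], reg_lambda: float = 1.0,
            tol: float = 1e-8) -> ClassifierModel:
    """Fit the L2-penalized softmax regression.

    Features are z-scored by the training mean/SD; the optimizer minimizes
    the negative multinomial log-likelihood plus (lambda/2)*||W||^2 over the
    non-intercept weights — a strictly convex problem, so the fit is
    deterministic for fixed data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ClassifierError("X must be (n_subjects, n_features) matching y")
    classes_present = np.unique(y)
    if classes_present.size < 2:
        raise ClassifierError("training labels contain a single class")
    counts = np.bincount(y)
    if np.any(counts[classes_present] < 2):
        raise ClassifierError("need at least 2 subjects per class")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD: invariant under dataset duplication
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i) for i in constant]
        raise ClassifierError(f"constant feature(s): {', '.join(names)}")
    Z = (X - mean) / sd

    n, d = Z.shape
    n_classes = int(y.max()) + 1
    K = max(n_classes, 2)
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0

    def objective(w_flat: np.ndarray):
        W = w_flat.reshape(K - 1, d + 1)
        P = _softmax_probs(Z, W)
        nll = -np.sum(Y * np.log(np.clip(P, 1e-300, None)))
        penalty = 0.5 * reg_lambda * np.sum(W[:, :-1] ** 2)
        resid = P[:, 1:] - Y[:, 1:]          # (n, K-1)
        grad_w = resid.T @ Z + reg_lambda * W[:, :-1]
        grad_b = resid.sum(axis=0)
        grad = np.hstack([grad_w, grad_b[:, None]]).ravel()
        return nll + penalty, grad

    w0 = np.zeros((K - 1) * (d + 1))
    res = minimize(objective, w0, jac=True, method="L-BFGS-B",
                   options={"gtol": tol, "ftol": 1e-12, "maxiter": 2000})
    W = res.x.reshape(K - 1, d + 1)
    return ClassifierModel(weights=W, scaler_mean=mean, scaler_sd=sd,
                           reg_lambda=reg_lambda)


def predict_proba(model: ClassifierModel, x: np.ndarray) -> tuple[str, float]:
    """Predicted status label and the model's confidence in it."""
    probs = class_probabilities(model, np.atleast_2d(x))[0]
    k = int(np.argmax(probs))
    return model.classes[k], float(probs[k])


def class_probabilities(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Per-class probabilities, rows summing to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ClassifierError(
            f"expected {model.n_features} features, got {X.shape[1]}")
    return _softmax_probs(model.standardize(X), model.weights)


def loocv(X: np.ndarray, y: Sequence[int], reg_lambda: float = 1.0) -> np.ndarray:
    """Held-out probability of the impaired class for every subject.

    Subject i is scored by a model fitted without subject i; the scaler is
    re-estimated on each training fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 3:
        raise ClassifierError("leave-one-out needs at least 3 subjects")
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_mlr(X[mask], y[mask], reg_lambda=reg_lambda)
        probs[i] = class_probabilities(model, X[i:i + 1])[0, 1]
    return probs


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    sensitivity: float
    specificity: float
    threshold: float


def roc_analysis(probs: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve by threshold sweep, trapezoid AUC, and the Youden-J operating point.

    The AUC equals the probability that a randomly chosen positive outranks a
    randomly chosen negative (ties counted half).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("ROC needs both classes present")

    thresholds = np.concatenate([[np.inf], np.unique(probs)[::-1]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = probs >= t
        tpr[i] = np.sum(pred & (labels == 1)) / n_pos
        fpr[i] = np.sum(pred & (labels == 0)) / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = int(np.argmax(j[1:])) + 1  # skip the degenerate (0,0) point
    return RocResult(
        fpr=fpr, tpr=tpr, auc=auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
    )
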