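"""The circulating-miRNA relapse classifier.

A logistic regression on the levels of one or two circulating miRNAs
(miR-375 and/or miR-122 on the log2 scale: miR-16-normalised PCR levels, or
normalised sequencing counts), with

* a probability cutoff chosen to minimise the training misclassification
  count (candidates are midpoints between consecutive distinct fitted
  probabilities plus boundary candidates);
* leave-one-out cross-validation in which every fold refits both the model
  and the cutoff without ever seeing the held-out label; and
* a full-train / external-test mode for validating the signature on an
  independent cohort.

Features are z-scored internally (and coefficients back-transformed for
reporting), so any positive affine rescaling of a feature leaves every
prediction unchanged. Complete separation is handled by a tiny L2 ridge
(1e-4) on the slopes, with ``converged=False`` recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .valstats import NEGATIVE_LABEL, POSITIVE_LABEL

__all__ = [
    "LogisticModel",
    "CutoffRule",
    "fit_logistic",
    "predict_proba",
    "choose_cutoff",
    "loocv_classify",
    "train_full_predict_external",
]

RIDGE = 1e-4
MAX_ITER = 50
SCORE_TOL = 1e-8


@dataclass
class LogisticModel:
    intercept: float
    coefficients: dict[str, float]
    converged: bool
    n_iterations: int
    # internal standardisation parameters, kept so external data is scaled
    # with the training statistics
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("model needs at least one feature")


@dataclass(frozen=True)
class CutoffRule:
    cutoff: float
    training_error: int

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie strictly inside (0, 1)")


def _as_label_array(labels: Sequence) -> np.ndarray:
    arr = pd.Series(list(labels))
    if arr.dtype == bool:
        return arr.to_numpy(dtype=float)
    mapped = arr.map({POSITIVE_LABEL: 1.0, NEGATIVE_LABEL: 0.0, True: 1.0, False: 0.0,
                      1: 1.0, 0: 0.0})
    if mapped.isna().any():
        raise ValueError(f"labels must be boolean or {POSITIVE_LABEL!r}/{NEGATIVE_LABEL!r}")
    return mapped.to_numpy(dtype=float)


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0
) -> tuple[np.ndarray, bool, int]:
    """Newton/IRLS for logistic MLE; ridge penalises the slopes only."""
    n, k = X.shape
    beta = np.zeros(k)
    penalty = np.zeros(k)
    penalty[1:] = ridge
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = np.clip(X @ beta, -35.0, 35.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        score = X.T @ (y - p) - penalty * beta
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = (X * w[:, None]).T @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        # dampen huge steps (divergence under separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step = step * (10.0 / norm)
        beta = beta + step
    return beta, converged, it


def fit_logistic(features: pd.DataFrame, labels: Sequence) -> LogisticModel:
    """Maximum-likelihood logistic regression with internal z-scoring.

    Zero-variance features receive coefficient 0 and do not enter the fit.
    Under complete separation (the unpenalised fit diverges) the model is
    refitted with an L2 ridge of 1e-4 on the slopes and ``converged`` is
    recorded False. Single-class labels are an error.
    """
    y = _as_label_array(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if features.shape[0] != y.size:
        raise ValueError("one label per sample row required")
    names = list(features.columns)
    vals = features.to_numpy(dtype=float)
    means = vals.mean(axis=0)
    sds = vals.std(axis=0)
    active = sds > 0
    Z = np.ones((vals.shape[0], 1 + int(active.sum())))
    if active.any():
        Z[:, 1:] = (vals[:, active] - means[active]) / sds[active]

    beta, converged, it = _irls_logistic(Z, y)
    if not converged or np.max(np.abs(beta)) > 30.0:
        beta, _, it = _irls_logistic(Z, y, ridge=RIDGE)
        converged = False

    coef_z = np.zeros(len(names))
    coef_z[active] = beta[1:]
    slopes = np.where(active, coef_z / np.where(active, sds, 1.0), 0.0)
    intercept = float(beta[0] - np.sum(slopes * means))
    return LogisticModel(
        intercept=intercept,
        coefficients={n: float(s) for n, s in zip(names, slopes)},
        converged=converged,
        n_iterations=it,
        feature_means={n: float(mu) for n, mu in zip(names, means)},
        feature_sds={n: float(sd) for n, sd in zip(names, sds)},
    )


def predict_proba(model: LogisticModel, features: pd.DataFrame) -> pd.Series:
    """Predicted relapse probability per sample row."""
    missing = [n for n in model.coefficients if n not in features.columns]
    if missing:
        raise ValueError(f"features missing from input: {missing}")
    eta = np.full(features.shape[0], model.intercept)
    for name, coef in model.coefficients.items():
        eta = eta + coef * features[name].to_numpy(dtype=float)
    eta = np.clip(eta, -35.0, 35.0)
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=features.index, name="probability")


def choose_cutoff(probabilities: Sequence[float], labels: Sequence) -> CutoffRule:
    """Probability cutoff minimising the training misclassification count.

    A sample is called positive ('relapsed') when its probability is strictly
    greater than the cutoff. Candidates are the midpoints between consecutive
    distinct sorted probabilities plus the two boundary midpoints toward 0 and
    1. Ties are broken toward the candidate with the largest margin to the
    nearest probability, then the smallest cutoff value.
    """
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    y = _as_label_array(labels)
    distinct = np.unique(p)
    candidates = [distinct[0] / 2.0]
    candidates += list((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append((distinct[-1] + 1.0) / 2.0)
    candidates = [c for c in candidates if 0.0 < c < 1.0]
    if not candidates:  # all probabilities at 0 and/or 1
        candidates = [0.5]

    best: tuple[int, float, float] | None = None  # (error, -margin, cutoff)
    for c in candidates:
        pred = p > c
        err = int(np.sum(pred != (y == 1.0)))
        margin = float(np.min(np.abs(p - c)))
        key = (err, -margin, c)
        if best is None or key < best:
            best = key
    return CutoffRule(cutoff=best[2], training_error=best[0])


def _prediction_frame(
    index: pd.Index, probs: np.ndarray, cutoff: np.ndarray, flagged: np.ndarray
) -> pd.DataFrame:
    labels = np.where(probs > cutoff, POSITIVE_LABEL, NEGATIVE_LABEL)
    return pd.DataFrame(
        {"probability": probs, "predicted": labels, "cutoff": cutoff, "flagged": flagged},
        index=index,
    )


def loocv_classify(features: pd.DataFrame, labels: Sequence) -> pd.DataFrame:
    """Leave-one-out cross-validated predictions.

    For every sample, the logistic model and the cutoff are refitted on the
    other n-1 samples and applied to the held-out sample; no fold ever sees
    the held-out label. Folds whose training set collapses to a single class
    fall back to the training-set majority label and are flagged.
    """
    y = _as_label_array(labels)
    n = features.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    probs = np.empty(n)
    cutoffs = np.empty(n)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        X_train = features.iloc[mask]
        if len(np.unique(y_train)) < 2:
            majority = float(y_train.mean() > 0.5)
            probs[i] = majority
            cutoffs[i] = 0.5
            flagged[i] = True
            continue
        model = fit_logistic(X_train, y_train)
        rule = choose_cutoff(predict_proba(model, X_train).to_numpy(), y_train)
        probs[i] = float(predict_proba(model, features.iloc[[i]]).iloc[0])
        cutoffs[i] = rule.cutoff
    return _prediction_frame(features.index, probs, cutoffs, flagged)


def train_full_predict_external(
    train_features: pd.DataFrame,
    train_labels: Sequence,
    test_features: pd.DataFrame,
) -> pd.DataFrame:
    """Fit one model + cutoff on the full training cohort, predict a test cohort.

    Feature columns must match; test features are scaled by the training
    standardisation (handled inside the model's back-transformed
    coefficients). An empty test set yields an empty prediction frame.
    """
    if list(train_features.columns) != list(test_features.columns):
        raise ValueError(
            f"feature mismatch: train {list(train_features.columns)} "
            f"vs test {list(test_features.columns)}"
        )
    model = fit_logistic(train_features, train_labels)
    rule = choose_cutoff(
        predict_proba(model, train_features).to_numpy(), train_labels
    )
    if test_features.shape[0] == 0:
        return _prediction_frame(test_features.index, np.empty(0),
                                 np.empty(0), np.zeros(0, dtype=bool))
    probs = predict_proba(model, test_features).to_numpy()
    cutoff = np.full(probs.size, rule.cutoff)
    return _prediction_frame(test_features.index, probs, cutoff,
                             np.zeros(probs.size, dtype=bool))
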