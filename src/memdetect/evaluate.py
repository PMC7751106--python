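"""Evaluation harness: confusion counts, the four headline metrics, ROC/AUC,
leave-one-out and stratified k-fold cross-validation.

Metrics follow the standard binary-classification definitions with membrane
as the positive class: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy (TP+TN)/n, and the Matthews correlation coefficient.  When any MCC
denominator factor is zero (e.g. a single-class prediction) the coefficient
is defined as 0 — the "no better than random" value.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import clone
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Sensitivity/specificity/accuracy in [0,1], MCC in [-1,1], optional AUC."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float | None = None

    def as_percent(self) -> dict[str, float]:
        """Headline numbers the way they are usually tabulated (two decimals)."""
        out = {
            "sensitivity": round(100 * self.sensitivity, 2),
            "specificity": round(100 * self.specificity, 2),
            "accuracy": round(100 * self.accuracy, 2),
            "mcc": round(self.mcc, 4),
        }
        if self.auc is not None:
            out["auc"] = round(self.auc, 4)
        return out


def confusion(pred, truth) -> ConfusionCounts:
    """Confusion counts with membrane (1) as the positive class."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


def metrics(cc: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """The four headline metrics from confusion counts."""
    if cc.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated samples")
    tp, fp, tn, fn = cc.tp, cc.fp, cc.tn, cc.fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / cc.total
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom2) if denom2 > 0 else 0.0
    return MetricsReport(sens, spec, acc, float(mcc), auc)


def counts_from_rates(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionCounts:
    """Confusion counts implied by class sizes and sensitivity/specificity.

    Rates are rounded to the nearest whole count, so tabulated percentages
    can be turned back into the confusion matrix they summarize.
    """
    tp = round(sensitivity * n_pos)
    tn = round(specificity * n_neg)
    return ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def roc_auc(scores, truth) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr) and the AUC.

    AUC is the trapezoidal area, equivalent to the midrank (tie-averaged)
    probability that a positive outscores a negative.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(set(truth.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(truth, scores)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))


def _score_or_label(est, X) -> np.ndarray:  # noqa: N803
    if hasattr(est, "predict_score"):
        return np.asarray(est.predict_score(X), dtype=float)
    if hasattr(est, "predict_proba"):
        return np.asarray(est.predict_proba(X))[:, 1]
    return np.asarray(est.predict(X), dtype=float)


def loocv(
    estimator, X, y, use_fast_path: bool = True
) -> tuple[np.ndarray, np.ndarray, MetricsReport]:
    """Leave-one-out cross-validation: each sample predicted from the rest.

    Neighbor-based estimators expose ``loo_predict`` (a masked precomputed
    distance matrix), which this harness uses when available; other learners
    are refitted n times.  Returns (predictions, scores, report).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV needs at least two samples")
    if use_fast_path and hasattr(estimator, "loo_predict"):
        fitted = clone(estimator).fit(X, y)
        pred, score = fitted.loo_predict()
    else:
        pred = np.empty(n, dtype=int)
        score = np.empty(n, dtype=float)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            est = clone(estimator).fit(X[mask], y[mask])
            pred[i] = int(est.predict(X[i : i + 1])[0])
            score[i] = float(_score_or_label(est, X[i : i + 1])[0])
            mask[i] = True
    both = len(set(y.tolist())) == 2
    report = metrics(confusion(pred, y), roc_auc(score, y)[1] if both else None)
    return pred, score, report


def kfold(
    estimator,
    X,
    y,
    k: int,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray, MetricsReport]:
    """Stratified (by default) k-fold cross-validation.

    Every sample is predicted exactly once by a model fitted on the other
    folds.  A training fold missing one of the classes is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    pred = np.empty(n, dtype=int)
    score = np.empty(n, dtype=float)
    for train_idx, test_idx in splitter.split(X, y):
        if len(set(y[train_idx].tolist())) < 2:
            raise ValueError("a training fold lost one of the classes")
        est = clone(estimator).fit(X[train_idx], y[train_idx])
        pred[test_idx] = np.asarray(est.predict(X[test_idx]), dtype=int)
        score[test_idx] = _score_or_label(est, X[test_idx])
    both = len(set(y.tolist())) == 2
    report = metrics(confusion(pred, y), roc_auc(score, y)[1] if both else None)
    return pred, score, report


__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics",
    "counts_from_rates",
    "roc_auc",
    "roc_auc_score",
    "loocv",
    "kfold",
]
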