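"""Confusion-matrix metrics, ROC/AUC and stratified k-fold evaluation.

The positive class is TLE (label 1) throughout.  The nine derived
metrics are accuracy, precision, sensitivity, specificity, F1, MCC, NPV,
FPR and FNR; a ratio whose denominator is zero is reported as NaN with a
warning rather than silently coerced to 0 or 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger("fasf_tle")

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "classification_metrics",
    "roc_auc",
    "kfold_evaluate",
]

METRIC_NAMES = [
    "accuracy", "precision", "sensitivity", "specificity",
    "f1_score", "mcc", "npv", "fpr", "fnr",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvalReport:
    counts: ConfusionCounts
    metrics: dict[str, float]
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def to_json(self) -> str:
        payload = {
            "counts": vars(self.counts),
            "metrics": {
                k: (None if v is None or not np.isfinite(v) else float(v))
                for k, v in self.metrics.items()
            },
            "roc": [[float(a), float(b)] for a, b in self.roc],
            "auc": None if self.auc is None else float(self.auc),
        }
        return json.dumps(payload, indent=2)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Binary confusion counts with class 1 positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    values = set(np.unique(y_true)) | set(np.unique(y_pred))
    if not values <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(values)}")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator); reporting NaN", name)
        return float("nan")
    return num / den


def classification_metrics(counts: ConfusionCounts) -> EvalReport:
    """The nine confusion-matrix metrics; NaN where undefined."""
    if counts.total == 0:
        raise ValueError("no samples")
    TP, TN, FP, FN = counts.TP, counts.TN, counts.FP, counts.FN
    mcc_den = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    metrics = {
        "accuracy": (TP + TN) / counts.total,
        "precision": _ratio(TP, TP + FP, "precision"),
        "sensitivity": _ratio(TP, TP + FN, "sensitivity"),
        "specificity": _ratio(TN, TN + FP, "specificity"),
        "f1_score": _ratio(2 * TP, 2 * TP + FP + FN, "f1_score"),
        "mcc": _ratio(TP * TN - FP * FN, mcc_den, "mcc"),
        "npv": _ratio(TN, TN + FN, "npv"),
        "fpr": _ratio(FP, FP + TN, "fpr"),
        "fnr": _ratio(FN, FN + TP, "fnr"),
    }
    return EvalReport(counts, metrics)


def roc_auc(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points over all score thresholds and the trapezoidal AUC."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def kfold_evaluate(
    X,
    y,
    model_factory,
    k: int = 5,
    seed: int = 0,
    score_fn=None,
) -> dict:
    """Stratified k-fold evaluation with a fresh model per fold.

    ``model_factory()`` must return an unfitted estimator with
    fit/predict; if it also offers ``decision_scores`` (or
    ``predict_proba``), ROC/AUC is computed per fold.  Returns per-fold
    reports plus a mean/sd summary across folds.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[EvalReport] = []
    for train, test in skf.split(X, y):
        model = model_factory()
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        report = classification_metrics(confusion(y[test], pred))
        scores = None
        if score_fn is not None:
            scores = score_fn(model, X[test])
        elif hasattr(model, "decision_scores"):
            scores = model.decision_scores(X[test])
        elif hasattr(model, "predict_proba"):
            scores = model.predict_proba(X[test])[:, -1]
        if scores is not None and np.unique(y[test]).size == 2:
            report.roc, report.auc = roc_auc(y[test], scores)
        fold_reports.append(report)

    summary = {}
    for name in METRIC_NAMES:
        vals = np.array([r.metrics[name] for r in fold_reports], dtype=float)
        summary[name] = {"mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals))}
    aucs = [r.auc for r in fold_reports if r.auc is not None]
    if aucs:
        summary["auc"] = {"mean": float(np.mean(aucs)), "sd": float(np.std(aucs))}
    return {"folds": fold_reports, "summary": summary}
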