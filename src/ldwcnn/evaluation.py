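"""Confusion-based metrics, probability RMSE, and stratified k-fold CV.

Per-class counts follow the one-vs-rest convention (each class in turn
treated as positive), and the rate metrics are macro-averaged: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), F-score the
harmonic mean of precision and sensitivity.  Accuracy is pooled
(TP+TN)/(TP+TN+FP+FN) over the one-vs-rest counts, which for a confusion
matrix equals the trace rate averaged over classes.  RMSE is taken over the
(sample, class) cells of the softmax probability matrix against the one-hot
truth; a per-sample class-index variant is available behind a flag.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .clinical_io import ClinicalTable

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    per_class: dict[str, np.ndarray]  # keys TP/TN/FP/FN, arrays over classes
    pooled: dict[str, int]
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f_score": self.f_score, "rmse": self.rmse, "n": self.n,
            "pooled": dict(self.pooled),
            "per_class": {k: v.tolist() for k, v in self.per_class.items()},
        }


def confusion(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int
              ) -> dict[str, np.ndarray]:
    """One-vs-rest TP/TN/FP/FN per class (pooled counts are their sums)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size and (max(y_true.max(), y_pred.max()) >= n_classes
                        or min(y_true.min(), y_pred.min()) < 0):
        raise ValueError("labels must lie in [0, n_classes)")
    cm = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    tp = np.diag(cm).astype(int)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fn - fp
    return {"TP": tp, "FN": fn, "FP": fp, "TN": tn}


def _safe_rate(num: np.ndarray, den: np.ndarray, name: str) -> float:
    valid = den > 0
    if not valid.all():
        logger.info("%s: classes %s excluded from macro average (zero denominator)",
                    name, np.flatnonzero(~valid).tolist())
    if not valid.any():
        return float("nan")
    return float(np.mean(num[valid] / den[valid]))


def compute_metrics(counts: dict[str, np.ndarray],
                    prob_matrix: np.ndarray | None = None,
                    y_true: Sequence[int] | None = None,
                    rmse_kind: str = "probability") -> MetricsReport:
    """Macro-averaged rates from one-vs-rest counts, plus probability RMSE.

    ``rmse_kind='probability'`` (default) measures sqrt(mean((p - onehot)^2))
    over all (sample, class) cells; ``'class_index'`` measures RMSE between
    the argmax class index and the true index.
    """
    tp, tn = counts["TP"].astype(float), counts["TN"].astype(float)
    fp, fn = counts["FP"].astype(float), counts["FN"].astype(float)
    total = tp + tn + fp + fn
    n = int(total[0]) if total.size else 0  # per class each sample appears once
    accuracy = float((tp + tn).sum() / total.sum()) if total.sum() else float("nan")
    sensitivity = _safe_rate(tp, tp + fn, "sensitivity")
    specificity = _safe_rate(tn, tn + fp, "specificity")
    precision = _safe_rate(tp, tp + fp, "precision")
    with np.errstate(invalid="ignore"):
        per_prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        per_sens = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
        per_f = 2 * per_prec * per_sens / (per_prec + per_sens)
    valid_f = np.isfinite(per_f)
    f_score = float(np.mean(per_f[valid_f])) if valid_f.any() else float("nan")

    rmse = float("nan")
    if prob_matrix is not None and y_true is not None:
        P = np.asarray(prob_matrix, dtype=float)
        y = np.asarray(y_true, dtype=int)
        if rmse_kind == "probability":
            onehot = np.eye(P.shape[1])[y]
            rmse = float(np.sqrt(np.mean((P - onehot) ** 2)))
        elif rmse_kind == "class_index":
            rmse = float(np.sqrt(np.mean((P.argmax(axis=1) - y) ** 2)))
        else:
            raise ValueError(f"unknown rmse_kind {rmse_kind!r}")

    pooled = {k: int(v.sum()) for k, v in counts.items()}
    return MetricsReport({k: v.copy() for k, v in counts.items()}, pooled,
                         accuracy, sensitivity, specificity, precision,
                         f_score, rmse, n)


def metrics_from_predictions(y_true, y_pred, prob_matrix, n_classes: int,
                             rmse_kind: str = "probability") -> MetricsReport:
    return compute_metrics(confusion(y_true, y_pred, n_classes),
                           prob_matrix, y_true, rmse_kind)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint, exhaustive, stratified test-fold index sets."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels)
    small = np.flatnonzero((counts > 0) & (counts < k))
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer than k={k} rows; use a smaller k")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(labels), labels)]


def kfold_cv(pipeline: Callable[[ClinicalTable, ClinicalTable],
                                tuple[np.ndarray, np.ndarray]] | object,
             table: ClinicalTable, k: int = 10, seed: int = 0,
             rmse_kind: str = "probability"
             ) -> tuple[list[MetricsReport], dict[str, tuple[float, float]]]:
    """Stratified k-fold cross-validation of a fit/predict pipeline.

    ``pipeline`` is either a callable ``(train_table, test_table) ->
    (y_pred, prob_matrix)`` — all preprocessing is expected to be re-fit on
    the training fold inside the callable, avoiding leakage — or a
    PipelineConfig, which is wrapped through the orchestrator.  Each row is
    evaluated exactly once; the summary reports the mean and sd of each
    metric across folds.
    """
    if not callable(pipeline):
        from .pipeline import fold_runner  # lazy: pipeline imports this module
        pipeline = fold_runner(pipeline)
    folds = stratified_folds(table.labels, k, seed)
    n_classes = len(table.label_set)
    all_idx = np.arange(table.n_rows)
    reports: list[MetricsReport] = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        y_pred, prob = pipeline(table.take(train_idx), table.take(test_idx))
        reports.append(metrics_from_predictions(table.labels[test_idx], y_pred,
                                                prob, n_classes, rmse_kind))
    keys = ("accuracy", "sensitivity", "specificity", "precision", "f_score", "rmse")
    summary = {}
    for key in keys:
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        summary[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
    return reports, summary


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def write_metrics_json(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def write_cv_csv(reports: list[MetricsReport],
                 summary: dict[str, tuple[float, float]], path: str | Path) -> None:
    """Flat CSV: one row per fold plus a mean summary row."""
    keys = ("accuracy", "sensitivity", "specificity", "precision", "f_score", "rmse")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fold", *keys])
        for i, r in enumerate(reports):
            w.writerow([i, *(getattr(r, k) for k in keys)])
        w.writerow(["mean", *(summary[k][0] for k in keys)])
        w.writerow(["sd", *(summary[k][1] for k in keys)])
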