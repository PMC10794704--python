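"""Multi-metric evaluation: confusion matrix, one-vs-rest precision /
recall / F1, accuracy, Cohen's kappa, and the micro-averaged ROC curve.

All metrics are computed from first principles on the K x K confusion
matrix (rows = true class, columns = predicted class) via the one-vs-rest
reduction:

    precision_c = TP / (TP + FP)        recall_c = TP / (TP + FN)
    F1_c = 2 P R / (P + R)              accuracy = trace / total
    kappa = (p_o - p_e) / (1 - p_e),    p_e = sum_c row_c * col_c / total^2

Aggregate precision/recall/F1 are unweighted macro means by default (the
weighted variant is available via ``average="weighted"``).  Zero
denominators yield 0 with a warning.  The micro-averaged ROC flattens all
N*K one-vs-rest (indicator, score) pairs before the threshold sweep and
integrates the AUC trapezoidally.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "ROCCurve",
    "confusion_matrix",
    "classification_metrics",
    "cohen_kappa",
    "micro_roc",
    "evaluate_model",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows = true, cols = predicted
    class_names: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred"] + list(self.class_names))
            for name, row in zip(self.class_names, self.counts):
                w.writerow([name] + [int(v) for v in row])


@dataclass
class MetricReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    kappa: float
    support: dict[str, int]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fpr", "tpr"])
            for f, t in zip(self.fpr, self.tpr):
                w.writerow([float(f), float(t)])


def confusion_matrix(y_true, y_pred, k: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    """counts[i, j] = #{true == i and pred == j}."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if y_true.size and (y_true.min() < 0 or y_true.max() >= k
                        or y_pred.min() < 0 or y_pred.max() >= k):
        raise ValueError(f"labels out of range [0, {k})")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    if class_names is None:
        class_names = [str(i) for i in range(k)]
    return ConfusionMatrix(counts=counts, class_names=list(class_names))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.warning("zero denominator in %s; defining the metric as 0", what)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix,
                           average: str = "macro") -> MetricReport:
    """Per-class one-vs-rest metrics plus aggregates from a confusion matrix."""
    counts = np.asarray(cm.counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    k = counts.shape[0]
    tp = np.diag(counts)
    row = counts.sum(axis=1)  # true-class totals (TP + FN)
    col = counts.sum(axis=0)  # predicted totals (TP + FP)
    precision, recall, f1 = {}, {}, {}
    pvals = np.zeros(k)
    rvals = np.zeros(k)
    fvals = np.zeros(k)
    for c in range(k):
        name = cm.class_names[c]
        p = _safe_div(tp[c], col[c], f"precision[{name}]")
        r = _safe_div(tp[c], row[c], f"recall[{name}]")
        f = _safe_div(2 * p * r, p + r, f"f1[{name}]")
        precision[name], recall[name], f1[name] = p, r, f
        pvals[c], rvals[c], fvals[c] = p, r, f
    if average == "weighted":
        w = row / total
        agg = (float(pvals @ w), float(rvals @ w), float(fvals @ w))
    else:
        agg = (float(pvals.mean()), float(rvals.mean()), float(fvals.mean()))
    return MetricReport(
        accuracy=float(tp.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=agg[0],
        macro_recall=agg[1],
        macro_f1=agg[2],
        kappa=cohen_kappa(cm),
        support={cm.class_names[c]: int(row[c]) for c in range(k)},
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    counts = np.asarray(cm.counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float(counts.sum(axis=1) @ counts.sum(axis=0)) / total ** 2
    if p_e == 1.0:
        raise ValueError("kappa undefined: expected agreement p_e = 1 "
                         "(single-category marginals)")
    return float((p_o - p_e) / (1.0 - p_e))


def micro_roc(y_true, probs) -> ROCCurve:
    """Micro-averaged ROC: flatten all N*K one-vs-rest pairs, sweep thresholds.

    At threshold t a pair is predicted positive when its score >= t; the
    curve runs from (0, 0) to (1, 1) and the AUC is the trapezoidal
    integral.
    """
    y_true = np.asarray(y_true)
    probs = np.asarray(probs, dtype=np.float64)
    n, k = probs.shape
    onehot = np.zeros((n, k), dtype=bool)
    onehot[np.arange(n), y_true] = True
    labels = onehot.ravel()
    scores = probs.ravel()
    pos = labels.sum()
    neg = labels.size - pos
    if pos == 0 or neg == 0:
        raise ValueError("micro ROC undefined: only one class after flattening")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp_cum = np.cumsum(l_sorted)
    fp_cum = np.cumsum(~l_sorted)
    # one operating point per distinct score (the last index of each run)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, labels.size - 1]
    tpr = np.r_[0.0, tp_cum[idx] / pos]
    fpr = np.r_[0.0, fp_cum[idx] / neg]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def evaluate_model(model, x: np.ndarray, y: np.ndarray,
                   class_names: list[str] | None = None):
    """Predict, then produce (MetricReport, ConfusionMatrix, ROCCurve).

    ``model`` exposes ``predict_proba``; predictions are the argmax of the
    class probabilities (numpy argmax: ties break to the lowest index).
    Images are scaled exactly as during training.
    """
    from .model import prepare_batch

    y = np.asarray(y)
    probs = model.predict_proba(prepare_batch(x))
    y_pred = probs.argmax(axis=1)
    k = probs.shape[1]
    cm = confusion_matrix(y, y_pred, k, class_names)
    report = classification_metrics(cm)
    roc = micro_roc(y, probs)
    return report, cm, roc
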