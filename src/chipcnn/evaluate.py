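"""Confusion matrices, one-vs-rest metrics, macro averages and ROC/AUC.

Per level, the 4x4 confusion matrix (rows = actual, columns = predicted) is
reduced to binary counts TP/FN/FP/TN and the six classification metrics are
computed:

    accuracy    = (TP+TN)/(TP+TN+FP+FN)     precision = TP/(TP+FP)
    recall      = sensitivity = TP/(TP+FN)  F1 = 2 P R/(P+R)
    specificity = TN/(TN+FP)

All metrics are reported in percent.  ROC curves sweep every distinct score
threshold in descending order (tied scores grouped) and AUC is the
trapezoidal area under (FPR, TPR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_LEVELS = 4
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "sensitivity", "specificity")

__all__ = [
    "ConfusionMatrix", "OneVsRestCounts", "MetricsReport",
    "confusion_matrix", "one_vs_rest", "metrics", "roc_auc",
    "macro_summary", "evaluate_predictions", "summarize_folds",
]


@dataclass
class ConfusionMatrix:
    """4x4 counts; integers per fold, reals when fold-averaged."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_LEVELS, N_LEVELS):
            raise ValueError("confusion matrix must be 4x4")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix entries must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [f"Level {i}" for i in range(N_LEVELS)]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


@dataclass(frozen=True)
class OneVsRestCounts:
    """Binary reduction of the multi-class matrix for one level."""

    TP: float
    FN: float
    FP: float
    TN: float


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Counts[i, j] = number of samples with actual level i predicted as j."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    for name, arr in [("true", y_true), ("predicted", y_pred)]:
        if arr.size and (arr.min() < 0 or arr.max() >= N_LEVELS):
            raise ValueError(f"{name} labels must lie in 0..{N_LEVELS - 1}")
    counts = np.zeros((N_LEVELS, N_LEVELS))
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def one_vs_rest(cm: ConfusionMatrix, level: int) -> OneVsRestCounts:
    """TP/FN/FP/TN of ``level`` against all other levels."""
    if level not in range(N_LEVELS):
        raise ValueError("level must be in 0..3")
    c = cm.counts
    tp = c[level, level]
    fn = c[level].sum() - tp
    fp = c[:, level].sum() - tp
    tn = c.sum() - tp - fn - fp
    return OneVsRestCounts(TP=float(tp), FN=float(fn), FP=float(fp), TN=float(tn))


def metrics(counts: OneVsRestCounts) -> dict[str, float]:
    """The six one-vs-rest metrics, in percent.

    A metric whose denominator is zero is returned as NaN (undefined) rather
    than silently 0.
    """
    tp, fn, fp, tn = counts.TP, counts.FN, counts.FP, counts.TN

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "sensitivity": recall,
        "specificity": ratio(tn, tn + fp),
    }


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC for one level's one-vs-rest scores.

    ``scores`` are the softmax scores for the target level, ``labels`` the
    binary one-vs-rest ground truth.  Thresholds sweep the distinct scores
    in descending order (ties grouped); the curve runs from (0, 0) to (1, 1).
    Returns ``(points, auc)`` with points as an (m, 2) array of (FPR, TPR).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.nonzero(np.diff(s))[0]          # last index of each tie group
    idx = np.r_[distinct, s.size - 1]
    tpr = np.r_[0.0, tps[idx] / n_pos]
    fpr = np.r_[0.0, fps[idx] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class MetricsReport:
    """Per-level and macro metrics of one evaluation (one fold)."""

    cm: ConfusionMatrix
    per_level: pd.DataFrame          # index: level 0..3, columns: METRIC_NAMES
    macro: dict[str, float]          # unweighted mean over levels, percent
    roc_points: dict[int, np.ndarray] = field(default_factory=dict)
    auc: dict[int, float] = field(default_factory=dict)
    fold_id: int | None = None

    @property
    def overall_accuracy(self) -> float:
        """Plain multi-class accuracy, trace/total (fraction, not percent).

        Distinct from the one-vs-rest accuracy of the per-level metrics,
        which also credits true negatives."""
        return float(np.trace(self.cm.counts) / self.cm.total)

    def summary(self) -> str:
        lines = [f"Metrics report (fold {self.fold_id})",
                 self.per_level.round(1).to_string(),
                 "macro: " + ", ".join(f"{k}={v:.1f}" for k, v in self.macro.items())]
        if self.auc:
            lines.append("AUC: " + ", ".join(
                f"level {lv}={a:.2f}" for lv, a in sorted(self.auc.items())))
        return "\n".join(lines)


def _per_level_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    rows = {lv: metrics(one_vs_rest(cm, lv)) for lv in range(N_LEVELS)}
    return pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]


def evaluate_predictions(y_true, scores: np.ndarray,
                         fold_id: int | None = None) -> MetricsReport:
    """Full report from true labels and per-sample softmax score vectors.

    Predicted labels are the score argmax (ties toward the lowest index);
    ROC/AUC is computed one-vs-rest per level when both classes are present.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y_pred = scores.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred)
    per_level = _per_level_frame(cm)
    macro = {m: float(per_level[m].mean()) for m in METRIC_NAMES}
    roc_points, auc = {}, {}
    for lv in range(N_LEVELS):
        binary = (y_true == lv)
        if 0 < binary.sum() < binary.size:
            roc_points[lv], auc[lv] = roc_auc(scores[:, lv], binary)
    return MetricsReport(cm=cm, per_level=per_level, macro=macro,
                         roc_points=roc_points, auc=auc, fold_id=fold_id)


def macro_summary(reports: list[MetricsReport]) -> dict:
    """Fold-averaged summary: per-metric mean and sample sd (over folds) of
    the macro metrics, plus the element-wise fold-averaged confusion matrix."""
    if not reports:
        raise ValueError("need at least one fold report")
    table = pd.DataFrame([
        {**r.macro, "overall_accuracy": 100.0 * r.overall_accuracy}
        for r in reports])
    mean_cm = ConfusionMatrix(np.mean([r.cm.counts for r in reports], axis=0))
    sd = table.std(ddof=1) if len(reports) > 1 else table.iloc[0] * 0.0
    auc_levels = sorted(set().union(*(r.auc.keys() for r in reports)))
    mean_auc = {lv: float(np.mean([r.auc[lv] for r in reports if lv in r.auc]))
                for lv in auc_levels}
    return {"mean": table.mean().to_dict(), "sd": sd.to_dict(),
            "mean_confusion": mean_cm, "mean_auc": mean_auc,
            "per_fold": table}


def summarize_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean +- sd of each macro metric over folds, as a tidy frame."""
    summary = macro_summary(reports)
    return pd.DataFrame({"mean": summary["mean"], "sd": summary["sd"]})
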