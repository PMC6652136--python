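"""Classification metrics: confusion counts, accuracy, F1, ROC and AUC.

Accuracy is reported as a percentage, (TP+TN)/(TP+TN+FP+FN) * 100, and the
F1 score as 2TP/(2TP+FP+FN).  The ROC curve is built by sweeping the
decision threshold over the predicted scores and the AUC is the trapezoidal
integral of TPR over FPR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(y_true: np.ndarray, scores: np.ndarray,
                     threshold: float = 0.5) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y_true == 1))),
        tn=int(np.sum((pred == 0) & (y_true == 0))),
        fp=int(np.sum((pred == 1) & (y_true == 0))),
        fn=int(np.sum((pred == 0) & (y_true == 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    """Percentage of correctly classified cases."""
    if c.total == 0:
        raise ValueError("empty evaluation set")
    return 100.0 * (c.tp + c.tn) / c.total


def f1_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 0.0 if denom == 0 else 2.0 * c.tp / denom


def roc_points(y_true: np.ndarray,
               scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points of the threshold-swept ROC curve.

    Thresholds run over the distinct scores from +inf downwards, so the
    curve starts at (0, 0) and ends at (1, 1).
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    pos = max(int(np.sum(y_true == 1)), 1)
    neg = max(int(np.sum(y_true == 0)), 1)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep the last index of each tied score block
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tpr = np.concatenate(([0.0], tps[distinct] / pos))
    fpr = np.concatenate(([0.0], fps[distinct] / neg))
    return fpr, tpr


def auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr = roc_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


@dataclass
class FoldResult:
    confusion: ConfusionCounts
    accuracy: float
    f1: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray]


@dataclass
class EvalReport:
    """Per-fold metrics plus mean +/- SD aggregates."""

    folds: list[FoldResult] = field(default_factory=list)

    def add(self, y_true: np.ndarray, scores: np.ndarray,
            threshold: float = 0.5) -> FoldResult:
        c = confusion_counts(y_true, scores, threshold)
        fold = FoldResult(confusion=c, accuracy=accuracy(c), f1=f1_score(c),
                          auc=auc(y_true, scores),
                          roc=roc_points(y_true, scores))
        self.folds.append(fold)
        return fold

    def _agg(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return float(np.mean(vals)), sd

    @property
    def mean_accuracy(self) -> tuple[float, float]:
        return self._agg("accuracy")

    @property
    def mean_f1(self) -> tuple[float, float]:
        return self._agg("f1")

    @property
    def mean_auc(self) -> tuple[float, float]:
        return self._agg("auc")

    def summary(self) -> dict:
        acc, acc_sd = self.mean_accuracy
        f1, f1_sd = self.mean_f1
        a, a_sd = self.mean_auc
        return {
            "n_folds": len(self.folds),
            "accuracy_mean": acc, "accuracy_sd": acc_sd,
            "f1_mean": f1, "f1_sd": f1_sd,
            "auc_mean": a, "auc_sd": a_sd,
            "folds": [
                {"tp": f.confusion.tp, "tn": f.confusion.tn,
                 "fp": f.confusion.fp, "fn": f.confusion.fn,
                 "accuracy": f.accuracy, "f1": f.f1, "auc": f.auc}
                for f in self.folds],
        }
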