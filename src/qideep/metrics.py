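"""Evaluation surface: per-class precision/recall/F1, macro means,
accuracy, threshold-free AUC, percent changes, and aggregation of repeated
runs as mean ± sd with a 95% normal confidence interval.

All rate metrics are reported in percent, matching clinical reporting
convention; AUC stays on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ConfusionMatrix", "MetricsReport", "RunAggregate", "confusion",
           "prf1", "macro", "accuracy", "auc", "percent_change",
           "point_change", "aggregate", "STATE_NAMES"]

STATE_NAMES = ("low", "medium", "high", "attack")


@dataclass(frozen=True)
class ConfusionMatrix:
    """C×C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("confusion matrix must be square and nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true, pred, n_classes: int) -> ConfusionMatrix:
    true = np.asarray(true, int)
    pred = np.asarray(pred, int)
    if true.shape != pred.shape:
        raise ValueError("label vectors must have equal length")
    for lab in (true, pred):
        if lab.size and (lab.min() < 0 or lab.max() >= n_classes):
            raise ValueError("label out of range")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (true, pred), 1)
    return ConfusionMatrix(cm)


def prf1(cm: ConfusionMatrix, class_id: int) -> tuple[float, float, float]:
    """Precision, recall and F1 for one class, in percent.

    Degenerate denominators yield 0 (no positives predicted / present).
    """
    c = cm.counts
    tp = c[class_id, class_id]
    fp = c[:, class_id].sum() - tp
    fn = c[class_id, :].sum() - tp
    p = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly predicted samples, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.total


def auc(scores, binary_labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals the fraction of (positive, negative) pairs ranked correctly by
    the score, ties counted one half; threshold-free.
    """
    s = np.asarray(scores, float)
    y = np.asarray(binary_labels, int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def percent_change(old: float, new: float) -> float:
    """Relative change 100·(new − old)/old, in percent of the old value."""
    if old <= 0:
        raise ValueError("percent_change needs old > 0")
    return 100.0 * (new - old) / old


def point_change(old: float, new: float) -> float:
    """Absolute difference of two percentages (percentage points)."""
    return new - old


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 (in %), macro means, accuracy and the
    attack-state recall R(s); optional AUC for binary scores."""

    per_class: pd.DataFrame          # rows = states, cols = precision/recall/f1
    accuracy: float
    auc: float | None = None

    @classmethod
    def from_predictions(cls, true, pred, n_classes: int = 4,
                         scores=None, binary_labels=None) -> "MetricsReport":
        cm = confusion(true, pred, n_classes)
        rows = [prf1(cm, c) for c in range(n_classes)]
        names = STATE_NAMES[:n_classes] if n_classes <= 4 else range(n_classes)
        df = pd.DataFrame(rows, columns=["precision", "recall", "f1"],
                          index=list(names))
        a = None
        if scores is not None and binary_labels is not None:
            a = auc(scores, binary_labels)
        return cls(per_class=df, accuracy=accuracy(cm), auc=a)

    @property
    def macro_precision(self) -> float:
        return float(self.per_class["precision"].mean())

    @property
    def macro_recall(self) -> float:
        return float(self.per_class["recall"].mean())

    @property
    def macro_f1(self) -> float:
        return float(self.per_class["f1"].mean())

    @property
    def attack_recall(self) -> float:
        return float(self.per_class["recall"].iloc[-1])

    def to_flat_dict(self) -> dict[str, float]:
        out = {"accuracy": self.accuracy,
               "macro_precision": self.macro_precision,
               "macro_recall": self.macro_recall,
               "macro_f1": self.macro_f1,
               "attack_recall": self.attack_recall}
        for state, row in self.per_class.iterrows():
            for m in ("precision", "recall", "f1"):
                out[f"{state}_{m}"] = float(row[m])
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def macro(report: MetricsReport) -> dict[str, float]:
    """Unweighted macro means over the states."""
    return {"precision": report.macro_precision,
            "recall": report.macro_recall,
            "f1": report.macro_f1}


@dataclass
class RunAggregate:
    """Mean, sample sd (ddof=1) and 95% normal CI per metric over runs."""

    mean: pd.Series
    sd: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_runs: int

    def row(self, metric: str) -> dict[str, float]:
        return {"mean": float(self.mean[metric]), "sd": float(self.sd[metric]),
                "ci_low": float(self.ci_low[metric]),
                "ci_high": float(self.ci_high[metric])}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def aggregate(runs: list[MetricsReport]) -> RunAggregate:
    """Aggregate repeated-run reports: mean ± sd and mean ± 1.96·sd/√runs."""
    if len(runs) < 2:
        raise ValueError("aggregation needs at least 2 runs")
    df = pd.DataFrame([r.to_flat_dict() for r in runs])
    mean, sd = df.mean(), df.std(ddof=1)
    half = 1.96 * sd / np.sqrt(len(runs))
    return RunAggregate(mean=mean, sd=sd, ci_low=mean - half,
                        ci_high=mean + half, n_runs=len(runs))
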