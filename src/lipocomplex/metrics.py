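"""Confusion-matrix metrics and ROC-AUC.

Accuracy, sensitivity (recall on the complex-formed class), specificity,
precision and F1 follow their confusion-count definitions exactly;
zero-denominator cases yield an explicit ``None`` marker, never a silent
zero.  AUC is computed as the Mann-Whitney rank statistic — the
probability that a random positive outscores a random negative, ties
counted one half — which equals the area under the ROC curve and is
robust to tied scores.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not set(np.unique(v).tolist()) <= {0, 1, 0.0, 1.0, True, False}:
        raise ValueError(f"{name} must be binary 0/1")
    return v.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """TP/FP/TN/FN with 1 = complex formed as the positive class."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, F1 from counts."""
    accuracy = _ratio(c.tp + c.tn, c.n)
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    precision = _ratio(c.tp, c.tp + c.fp)
    if precision is None or sensitivity is None or (
        precision + sensitivity == 0
    ):
        f1 = None
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, precision=precision,
                         f1=f1)


def roc_auc(y_true, scores) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(score+ = score-)."""
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("length mismatch between labels and scores")
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = ranks[y_true == 1].sum()
    return float((rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(y_true, y_pred, scores=None) -> MetricsReport:
    """Full report backing the train/test metric tables."""
    report = metrics(confusion(y_true, y_pred))
    if scores is not None:
        report.auc = roc_auc(y_true, scores)
    return report
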