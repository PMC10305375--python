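"""Permutation importance of descriptors for a trained classifier.

Run on the no-PCA pipeline variant (component mixing would otherwise
spread each descriptor's contribution over all inputs): each descriptor
column is shuffled while the others stay fixed, and the drop in accuracy
relative to the unshuffled baseline is the descriptor's raw contribution.
Raw drops are averaged over repeats, floored at zero (a shuffle can
increase accuracy by chance; a negative contribution is noise, not
signal) and normalized to sum to one.  Within a repeat, a single shared
permutation is applied to every column, so two equally irrelevant
columns receive identical treatment and a provably ignored column scores
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import confusion, metrics


@dataclass
class ImportanceReport:
    feature_names: list[str]
    scores: np.ndarray          # normalized, sum to 1
    raw_drops: np.ndarray       # mean accuracy drop per descriptor
    baseline_accuracy: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.raw_drops = np.asarray(self.raw_drops, dtype=float)

    @property
    def ranking(self) -> list[int]:
        """Column indices by descending score; ties keep column order."""
        return list(np.argsort(-self.scores, kind="stable"))

    def top_k(self, k: int) -> list[tuple[str, float]]:
        if not 1 <= k <= len(self.feature_names):
            raise ValueError(
                f"k={k} outside [1, {len(self.feature_names)}]"
            )
        return [(self.feature_names[i], float(self.scores[i]))
                for i in self.ranking[:k]]


def _accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return metrics(confusion(y_true, y_pred)).accuracy


def permutation_importance(model, X, y, n_repeats: int = 10,
                           seed: int = 0,
                           feature_names: list[str] | None = None,
                           ) -> ImportanceReport:
    """Accuracy-based permutation importance for any object with a
    ``predict(X)`` method (or any callable returning labels)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    predict = model.predict if hasattr(model, "predict") else model
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"descriptor_{j:02d}" for j in range(p)]
    baseline = _accuracy(y, np.asarray(predict(X)))
    rng = np.random.default_rng(seed)
    drops = np.zeros((n_repeats, p))
    for r in range(n_repeats):
        perm = rng.permutation(n)  # one schedule shared by all columns
        for j in range(p):
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            drops[r, j] = baseline - _accuracy(y, np.asarray(predict(Xp)))
    raw = drops.mean(axis=0)
    floored = np.maximum(raw, 0.0)
    total = floored.sum()
    if total > 0:
        scores = floored / total
    else:
        # no column moves the accuracy: report a flat profile
        scores = np.full(p, 1.0 / p)
    return ImportanceReport(feature_names=list(feature_names),
                            scores=scores, raw_drops=raw,
                            baseline_accuracy=baseline)


def top_k_report(report: ImportanceReport, k: int) -> list[tuple[str, float]]:
    """First k (descriptor, score) entries of the ranking."""
    return report.top_k(k)
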