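"""Classic resampling baselines implemented from their definitions.

SMOTE oversamples the minority class by linear interpolation between a
minority point and one of its k nearest minority neighbors; ENN
(edited nearest neighbours) removes every sample whose label disagrees
with the majority vote of its k nearest neighbors; SMOTE-ENN is their
sequential composition.  All neighbor queries use Euclidean distance in
the (min-max normalized) feature space; sklearn's NearestNeighbors does
the index work.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors


def _minority_majority(y: np.ndarray) -> tuple[int, int]:
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    # ties: treat 1 (success) as minority, mirroring the augmentation target
    return (0, 1) if n0 < n1 else (1, 0)


def smote(X: np.ndarray, y: np.ndarray, k: int = 5,
          seed: int | np.random.Generator = 0,
          ) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolated synthetic minority rows.

    Each synthetic row is x + u * (x' - x) with x a uniformly drawn
    minority row, x' one of its k nearest minority neighbors (self
    excluded) and u ~ Uniform(0, 1).  Original rows are kept intact.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    minority, _ = _minority_majority(y)
    X_min = X[y == minority]
    n_min = X_min.shape[0]
    gap = int((y != minority).sum()) - n_min
    if gap <= 0:
        return X.copy(), y.copy()
    if n_min <= k:
        raise ValueError(
            f"SMOTE needs minority count > k; got {n_min} <= {k}"
        )
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    base = rng.integers(0, n_min, size=gap)
    pick = rng.integers(0, k, size=gap)
    u = rng.uniform(0.0, 1.0, size=gap)
    x0 = X_min[base]
    x1 = X_min[neighbors[base, pick]]
    synthetic = x0 + u[:, None] * (x1 - x0)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(gap, minority, dtype=int)])
    return X_out, y_out


def enn(X: np.ndarray, y: np.ndarray, k: int = 3,
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edited nearest neighbours: drop rows whose label loses the
    majority vote of their k nearest neighbors (self excluded).

    A row is removed only on strict disagreement (more than half the
    neighbors carry the other label).  Returns (X_kept, y_kept,
    kept_index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"ENN needs more than k={k} samples, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    neighbors = nn.kneighbors(X, return_distance=False)[:, 1:]
    disagree = (y[neighbors] != y[:, None]).sum(axis=1)
    keep = disagree <= k / 2.0
    kept_index = np.flatnonzero(keep)
    return X[kept_index], y[kept_index], kept_index


def smote_enn(X: np.ndarray, y: np.ndarray, smote_k: int = 5,
              enn_k: int = 3, seed: int | np.random.Generator = 0,
              ) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE followed by ENN editing of the oversampled set."""
    X_s, y_s = smote(X, y, k=smote_k, seed=seed)
    X_e, y_e, _ = enn(X_s, y_s, k=enn_k)
    return X_e, y_e


class SMOTEResampler(BaseEstimator):
    """fit_resample-style wrapper over :func:`smote`."""

    def __init__(self, k=5, random_state=0):
        self.k = k
        self.random_state = random_state

    def fit_resample(self, X, y):
        return smote(X, y, k=self.k, seed=self.random_state)


class ENNResampler(BaseEstimator):
    def __init__(self, k=3):
        self.k = k

    def fit_resample(self, X, y):
        X_e, y_e, _ = enn(X, y, k=self.k)
        return X_e, y_e


class SMOTEENNResampler(BaseEstimator):
    def __init__(self, smote_k=5, enn_k=3, random_state=0):
        self.smote_k = smote_k
        self.enn_k = enn_k
        self.random_state = random_state

    def fit_resample(self, X, y):
        return smote_enn(X, y, smote_k=self.smote_k, enn_k=self.enn_k,
                         seed=self.random_state)


class IdentityResampler(BaseEstimator):
    """No-op arm for resampling comparisons."""

    def fit_resample(self, X, y):
        return np.asarray(X, float).copy(), np.asarray(y, int).copy()
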