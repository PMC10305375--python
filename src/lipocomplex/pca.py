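"""PCA by explicit eigendecomposition of the training covariance.

The model keeps the full orthonormal eigenvector basis with eigenvalues
in descending order, so that scree/cumulative-variance reporting, the
85%-cumulative selection rule, a fixed-k override, and projection of any
split onto the leading k components are all available from one fit.
Covariance uses the unbiased (n-1) denominator; each eigenvector's
largest-magnitude entry is made positive so outputs are reproducible
despite the sign ambiguity of eigenvectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .table import DescriptorTable


class PCAReducer(TransformerMixin, BaseEstimator):
    """Principal-component reduction with scree-based component selection.

    Parameters
    ----------
    n_components : int or None
        Fixed number of components to keep at transform time.  ``None``
        selects the smallest k whose cumulative explained-variance ratio
        reaches ``cumulative_threshold``.
    cumulative_threshold : float
        Cumulative explained-variance level for automatic selection
        (default 0.85).
    """

    def __init__(self, n_components: int | None = None,
                 cumulative_threshold: float = 0.85):
        self.n_components = n_components
        self.cumulative_threshold = cumulative_threshold

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.mean_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        eigvecs = eigvecs[:, order]
        # sign convention: largest-|entry| of each component positive
        for j in range(eigvecs.shape[1]):
            i = np.argmax(np.abs(eigvecs[:, j]))
            if eigvecs[i, j] < 0:
                eigvecs[:, j] = -eigvecs[:, j]
        self.components_ = eigvecs
        self.eigenvalues_ = eigvals
        total = eigvals.sum()
        self.explained_variance_ratio_ = (
            eigvals / total if total > 0 else np.full_like(eigvals, np.nan)
        )
        self.n_features_in_ = X.shape[1]
        self.n_components_ = self.select_components()
        return self

    def scree(self) -> pd.DataFrame:
        """Table of (component, eigenvalue, cumulative explained
        variance); the cumulative column is non-decreasing and ends at 1."""
        check_is_fitted(self, "eigenvalues_")
        cumulative = np.cumsum(self.explained_variance_ratio_)
        return pd.DataFrame({
            "component": np.arange(1, len(self.eigenvalues_) + 1),
            "eigenvalue": self.eigenvalues_,
            "cumulative_explained_variance": cumulative,
        })

    def select_components(self, cumulative_threshold: float | None = None,
                          fixed_k: int | None = None) -> int:
        """Smallest k with cumulative ratio >= threshold; ``fixed_k``
        overrides the rule entirely."""
        check_is_fitted(self, "eigenvalues_")
        if fixed_k is None:
            fixed_k = self.n_components
        if fixed_k is not None:
            if not 1 <= fixed_k <= self.n_features_in_:
                raise ValueError(
                    f"fixed_k={fixed_k} outside [1, {self.n_features_in_}]"
                )
            return int(fixed_k)
        threshold = (self.cumulative_threshold if cumulative_threshold is None
                     else cumulative_threshold)
        cumulative = np.cumsum(self.explained_variance_ratio_)
        k = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
        return min(k, self.n_features_in_)

    def transform(self, X, k: int | None = None) -> np.ndarray:
        """(X - mean) projected onto the leading k components."""
        check_is_fitted(self, "components_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, fitted on {self.n_features_in_}"
            )
        if k is None:
            k = self.n_components_
        if not 1 <= k <= self.n_features_in_:
            raise ValueError(f"k={k} outside [1, {self.n_features_in_}]")
        return (X - self.mean_) @ self.components_[:, :k]

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "components_")
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        k = scores.shape[1]
        return scores @ self.components_[:, :k].T + self.mean_


def fit_pca(train: DescriptorTable | np.ndarray) -> PCAReducer:
    X = train.features if isinstance(train, DescriptorTable) else train
    return PCAReducer().fit(X)


def transform_table(model: PCAReducer, table: DescriptorTable,
                    k: int) -> DescriptorTable:
    """Project a descriptor table onto the leading k components; labels
    carried through unchanged."""
    scores = model.transform(table.features, k=k)
    names = [f"pc_{i + 1:02d}" for i in range(k)]
    return table.with_features(scores, feature_names=names)
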