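"""Min-max normalization fitted on the training split only.

Each descriptor x is rescaled by the training-set extrema,

    x_norm = (x - x_min) / (x_max - x_min),

so that training values land in [0, 1].  The identical affine map is then
applied to the test split, whose values may legitimately fall outside
[0, 1]; no clipping is performed.  Zero-range (constant) descriptors map
to 0, keeping them inert rather than producing NaN.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .table import DescriptorTable, TableError


@dataclass
class NormalizationParams:
    """Per-feature training minima and maxima, serializable for exact
    reuse at test time."""

    x_min: np.ndarray
    x_max: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if np.any(self.x_min > self.x_max):
            raise ValueError("x_min > x_max for some feature")
        if not (len(self.x_min) == len(self.x_max) == len(self.feature_names)):
            raise ValueError("params length mismatch")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            x_min=np.array(d["x_min"], dtype=float),
            x_max=np.array(d["x_max"], dtype=float),
            feature_names=list(d["feature_names"]),
        )

    def save(self, path: str | os.PathLike) -> None:
        payload = self.to_dict()
        with open(path, "w") as fh:
            if str(path).endswith((".yaml", ".yml")):
                yaml.safe_dump(payload, fh, sort_keys=False)
            else:
                json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "NormalizationParams":
        with open(path) as fh:
            if str(path).endswith((".yaml", ".yml")):
                payload = yaml.safe_load(fh)
            else:
                payload = json.load(fh)
        return cls.from_dict(payload)


class MinMaxNormalizer(TransformerMixin, BaseEstimator):
    """Leakage-safe min-max scaler over descriptor matrices.

    Unlike a generic scaler this keeps the fitted extrema addressable by
    feature name (for serialization alongside a trained model) and maps
    constant columns to 0 instead of relying on an arbitrary fallback
    scale.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.range_ = self.data_max_ - self.data_min_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, fitted on {self.n_features_in_}"
            )
        denom = np.where(self.range_ == 0, 1.0, self.range_)
        out = (X - self.data_min_) / denom
        out[:, self.range_ == 0] = 0.0
        return out

    def inverse_transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X)
        return X * self.range_ + self.data_min_


def fit_minmax(train: DescriptorTable) -> NormalizationParams:
    """Column-wise training extrema of a descriptor table."""
    if train.n_samples < 1:
        raise TableError("cannot fit normalization on an empty table")
    return NormalizationParams(
        x_min=train.features.min(axis=0),
        x_max=train.features.max(axis=0),
        feature_names=list(train.feature_names),
    )


def apply_minmax(params: NormalizationParams,
                 table: DescriptorTable) -> DescriptorTable:
    """Apply fitted min-max scaling to any split; labels untouched."""
    if list(table.feature_names) != list(params.feature_names):
        raise TableError("feature names do not match normalization params")
    rng = params.x_max - params.x_min
    denom = np.where(rng == 0, 1.0, rng)
    out = (table.features - params.x_min) / denom
    out[:, rng == 0] = 0.0
    return table.with_features(out)
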