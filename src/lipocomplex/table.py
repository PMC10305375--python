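"""Descriptor-table data model and CSV I/O.

A :class:`DescriptorTable` is the container every pipeline stage consumes:
a dense numeric matrix of molecular descriptors (one row per formulation
experiment), a binary complexation label per row (1 = the drug-phospholipid
complex formed, i.e. complexation rate >= 80%), ordered feature names, and
an optional grouping of each descriptor into one of the four blocks the
descriptors come from: the drug (``api``), the phospholipid (``lipid``),
the solvent (``solvent``) and the experimental conditions (``condition``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

VALID_GROUPS = ("api", "lipid", "solvent", "condition")

#: label strings accepted on read, mapped to {0, 1}
_LABEL_ALIASES = {
    "success": 1, "failure": 0,
    "yes": 1, "no": 0,
    "1": 1, "0": 0,
    "1.0": 1, "0.0": 0,
    "true": 1, "false": 0,
}


class TableError(ValueError):
    """Base class for descriptor-table validation failures."""


class MissingValueError(TableError):
    """A descriptor cell is empty or NaN."""


class NonNumericDataError(TableError):
    """A descriptor cell cannot be parsed as a number."""


class MissingLabelColumnError(TableError):
    """The requested label column is absent from the file."""


class LabelCardinalityError(TableError):
    """The label column has more than two levels, or levels that cannot
    be mapped onto {0, 1}."""


@dataclass
class ClassCounts:
    """Number of success (complex formed) and failure rows in a table."""

    n_success: int
    n_failure: int

    @property
    def n_total(self) -> int:
        return self.n_success + self.n_failure

    @property
    def gap(self) -> int:
        """Majority-minority difference; the number of minority rows an
        oversampler must add to balance the classes."""
        return abs(self.n_success - self.n_failure)

    def as_tuple(self) -> tuple[int, int]:
        return (self.n_success, self.n_failure)


@dataclass
class DescriptorTable:
    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    feature_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise TableError(
                f"features must be 2-D, got shape {self.features.shape}"
            )
        self.labels = np.asarray(self.labels)
        self.feature_names = list(self.feature_names)
        self._validate()
        self.labels = self.labels.astype(int)

    def _validate(self) -> None:
        n, p = self.features.shape
        if not np.isfinite(self.features).all():
            raise MissingValueError("features contain NaN or infinite values")
        if self.labels.shape != (n,):
            raise TableError(
                f"labels have shape {self.labels.shape}, expected ({n},)"
            )
        label_set = set(np.unique(self.labels).tolist())
        if not label_set <= {0, 1, 0.0, 1.0}:
            raise LabelCardinalityError(
                f"labels must be binary 0/1, found values {sorted(label_set)}"
            )
        if len(self.feature_names) != p:
            raise TableError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise TableError("feature names are not unique")
        if self.feature_groups:
            for name, group in self.feature_groups.items():
                if group not in VALID_GROUPS:
                    raise TableError(
                        f"feature {name!r}: unknown group {group!r}; "
                        f"expected one of {VALID_GROUPS}"
                    )
            missing = set(self.feature_names) - set(self.feature_groups)
            if missing:
                raise TableError(
                    f"features without a group assignment: {sorted(missing)}"
                )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> ClassCounts:
        return ClassCounts(
            n_success=int((self.labels == 1).sum()),
            n_failure=int((self.labels == 0).sum()),
        )

    def minority_label(self) -> int:
        """Label of the smaller class (ties broken toward 1, the success
        class, which is the minority the augmentation targets by default)."""
        c = self.class_counts()
        return 0 if c.n_failure < c.n_success else 1

    def with_features(self, features: np.ndarray,
                      feature_names: list[str] | None = None,
                      ) -> "DescriptorTable":
        """Copy of this table with the feature matrix (and optionally the
        names) replaced; labels and groups carried through."""
        names = feature_names if feature_names is not None else self.feature_names
        groups = self.feature_groups if feature_names is None else {}
        return DescriptorTable(
            features=features,
            labels=self.labels.copy(),
            feature_names=list(names),
            feature_groups=dict(groups),
        )

    def subset(self, idx: np.ndarray) -> "DescriptorTable":
        return DescriptorTable(
            features=self.features[idx],
            labels=self.labels[idx],
            feature_names=list(self.feature_names),
            feature_groups=dict(self.feature_groups),
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = self.labels
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DescriptorTable):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.features, other.features)
            and self.feature_groups == other.feature_groups
        )


def _map_labels(raw: pd.Series) -> np.ndarray:
    levels = pd.unique(raw.dropna())
    if len(levels) > 2:
        raise LabelCardinalityError(
            f"label column has {len(levels)} levels: {list(levels)[:5]}..."
        )
    out = np.empty(len(raw), dtype=int)
    for i, v in enumerate(raw):
        key = str(v).strip().lower()
        if key in _LABEL_ALIASES:
            out[i] = _LABEL_ALIASES[key]
        else:
            raise LabelCardinalityError(
                f"label value {v!r} cannot be mapped to 0/1"
            )
    return out


def read_table(path: str | os.PathLike, label_column: str = "label",
               groups_path: str | os.PathLike | None = None,
               ) -> DescriptorTable:
    """Read a descriptor CSV (header row, numeric descriptor columns, one
    label column) into a validated :class:`DescriptorTable`.

    Column order is preserved.  An optional sidecar YAML maps feature
    names to descriptor groups.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise MissingLabelColumnError(
            f"label column {label_column!r} not in {list(df.columns)}"
        )
    labels = _map_labels(df[label_column])
    feat_df = df.drop(columns=[label_column])
    feature_names = list(feat_df.columns)
    n, p = feat_df.shape
    features = np.empty((n, p), dtype=float)
    for j, name in enumerate(feature_names):
        col = feat_df[name]
        blank = col.str.strip() == ""
        if blank.any():
            row = int(np.argmax(blank.to_numpy()))
            raise MissingValueError(
                f"blank cell in column {name!r}, row {row}"
            )
        try:
            features[:, j] = col.astype(float)
        except ValueError as exc:
            raise NonNumericDataError(
                f"non-numeric value in column {name!r}: {exc}"
            ) from exc
    groups: dict[str, str] = {}
    if groups_path is not None:
        with open(groups_path) as fh:
            groups = yaml.safe_load(fh) or {}
    return DescriptorTable(features, labels, feature_names, groups)


def write_table(table: DescriptorTable, path: str | os.PathLike,
                label_column: str = "label",
                groups_path: str | os.PathLike | None = None) -> None:
    """Write a table as CSV with a header row.

    Floats are written with ``repr`` precision so that
    ``read_table(write_table(t))`` reproduces the features exactly.
    """
    df = table.to_frame(label_column)
    # str() of a float64 round-trips exactly in Python 3
    df.to_csv(path, index=False)
    if groups_path is not None and table.feature_groups:
        with open(groups_path, "w") as fh:
            yaml.safe_dump(table.feature_groups, fh, sort_keys=False)


def class_counts(table: DescriptorTable) -> ClassCounts:
    """Success/failure counts of a table (order-invariant)."""
    return table.class_counts()


def concat_tables(a: DescriptorTable, b: DescriptorTable) -> DescriptorTable:
    if a.feature_names != b.feature_names:
        raise TableError("cannot concatenate tables with different features")
    return DescriptorTable(
        features=np.vstack([a.features, b.features]),
        labels=np.concatenate([a.labels, b.labels]),
        feature_names=list(a.feature_names),
        feature_groups=dict(a.feature_groups),
    )
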