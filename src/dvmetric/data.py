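"""Labeled tabular datasets and their CSV/JSON round trip.

A :class:`LabeledDataset` is the package's in-memory container: an n x p
real feature matrix with a length-n label vector, either categorical
(classification / clustering ground truth) or continuous (regression
target).  CSV I/O keeps a header row of feature names plus one label
column; generated datasets get a JSON sidecar recording the generator
configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateLabelError, InputError

__all__ = ["LabeledDataset", "read_dataset", "write_dataset"]

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"


@dataclass
class LabeledDataset:
    """Feature matrix X (n x p) with per-sample labels Y."""

    features: np.ndarray
    labels: np.ndarray | None
    feature_names: list[str] = None
    label_kind: str = CATEGORICAL
    label_name: str = "label"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        if X.ndim != 2:
            raise InputError("features must be a 2-d matrix")
        if X.shape[0] < 2 or X.shape[1] < 1:
            raise InputError("need n >= 2 samples and p >= 1 features")
        if not np.all(np.isfinite(X)):
            raise InputError("features contain missing or non-finite entries")
        self.features = X
        if self.labels is not None:
            y = np.asarray(self.labels)
            if y.shape != (X.shape[0],):
                raise InputError(
                    f"label length {y.shape} does not match n = {X.shape[0]}")
            if self.label_kind == CONTINUOUS:
                y = y.astype(float)
                if not np.all(np.isfinite(y)):
                    raise InputError("labels contain non-finite entries")
            self.labels = y
        if self.label_kind not in (CATEGORICAL, CONTINUOUS):
            raise InputError(f"unknown label_kind {self.label_kind!r}")
        if self.feature_names is None:
            self.feature_names = [f"F{j}" for j in range(X.shape[1])]
        if len(self.feature_names) != X.shape[1]:
            raise InputError("feature_names arity does not match p")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise DegenerateLabelError("dataset has no labels")
        if self.label_kind == CATEGORICAL and len(np.unique(self.labels)) < 2:
            raise DegenerateLabelError("labels contain a single class")
        return self.labels

    def select_features(self, names_or_idx) -> "LabeledDataset":
        """Column subset by names or integer indices (order preserved)."""
        idx = []
        for item in names_or_idx:
            if isinstance(item, str):
                idx.append(self.feature_names.index(item))
            else:
                idx.append(int(item))
        return LabeledDataset(self.features[:, idx], self.labels,
                              [self.feature_names[i] for i in idx],
                              self.label_kind, self.label_name,
                              dict(self.meta))

    def subsample(self, n: int | None = None, p: int | None = None,
                  seed: int = 0) -> "LabeledDataset":
        """Seeded subsample of rows and/or feature columns (no replacement)."""
        from .exceptions import BoundsError

        rng = np.random.default_rng(seed)
        rows = np.arange(self.n)
        cols = np.arange(self.p)
        if n is not None:
            if n > self.n:
                raise BoundsError(f"requested n={n} exceeds dataset n={self.n}")
            rows = np.sort(rng.choice(self.n, size=n, replace=False))
        if p is not None:
            if p > self.p:
                raise BoundsError(f"requested p={p} exceeds dataset p={self.p}")
            cols = np.sort(rng.choice(self.p, size=p, replace=False))
        labels = None if self.labels is None else self.labels[rows]
        return LabeledDataset(self.features[np.ix_(rows, cols)], labels,
                              [self.feature_names[j] for j in cols],
                              self.label_kind, self.label_name,
                              dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        if self.labels is not None:
            df[self.label_name] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str | None,
                   label_kind: str | None = None) -> "LabeledDataset":
        if label_column is not None and label_column not in df.columns:
            raise InputError(
                f"label column {label_column!r} not found; columns are "
                f"{list(df.columns)}")
        labels = None
        if label_column is not None:
            labels = df[label_column].to_numpy()
            df = df.drop(columns=[label_column])
            if label_kind is None:
                label_kind = (CONTINUOUS if labels.dtype.kind == "f"
                              else CATEGORICAL)
        bad = [c for c in df.columns
               if not np.issubdtype(df[c].dtype, np.number)]
        if bad:
            raise InputError(f"non-numeric feature columns: {bad}")
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)].tolist()[:5]
            cols = df.columns[df.isna().any()].tolist()
            raise InputError(
                f"missing values in columns {cols} (first rows {rows})")
        return cls(df.to_numpy(dtype=float), labels,
                   [str(c) for c in df.columns],
                   label_kind or CATEGORICAL,
                   label_column or "label")


def read_dataset(path, label_column: str | None,
                 label_kind: str | None = None) -> LabeledDataset:
    """Read a CSV (header row required) into a :class:`LabeledDataset`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return LabeledDataset.from_frame(df, label_column, label_kind)


def write_dataset(dataset: LabeledDataset, path, sidecar: dict | None = None
                  ) -> Path:
    """Write a dataset to CSV; optionally write a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees binary float round-trip through the CSV
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")
    if sidecar is not None or dataset.meta:
        payload = dict(dataset.meta)
        if sidecar:
            payload.update(sidecar)
        path.with_suffix(".json").write_text(
            json.dumps(payload, indent=2, default=str))
    return path
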