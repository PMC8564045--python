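"""Labelled feature tables: the common in-memory container of the package.

A :class:`FeatureTable` wraps a pandas DataFrame whose reserved columns are
``sample_id`` (unique string identifier), ``label`` (0 = control, 1 = case)
and ``fold`` (``TRAIN`` or ``TEST``); every remaining numeric column is a
feature.  Sphere benchmarks additionally carry a ``radius`` column, kept on
the side so it never leaks into the feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

RESERVED_COLUMNS = ("sample_id", "label", "fold", "radius")

TRAIN = "TRAIN"
TEST = "TEST"


@dataclass
class FeatureTable:
    """Samples x features matrix with identifiers, binary labels and folds.

    Parameters
    ----------
    features : DataFrame
        Numeric feature columns, one row per sample.
    labels : ndarray of {0, 1}
        Binary class labels; 0 = control, 1 = case.
    folds : ndarray of str
        ``"TRAIN"`` / ``"TEST"`` assignment per sample.
    sample_ids : ndarray of str
        Unique sample identifiers.
    """

    features: pd.DataFrame
    labels: np.ndarray
    folds: np.ndarray
    sample_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.features = pd.DataFrame(self.features).reset_index(drop=True)
        n = len(self.features)
        self.labels = np.asarray(self.labels, dtype=int)
        self.folds = np.asarray(self.folds, dtype=object)
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:05d}" for i in range(n)], dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if not (len(self.labels) == len(self.folds) == len(self.sample_ids) == n):
            raise SchemaError("labels, folds and sample_ids must match the row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise SchemaError("labels must be binary (0 = control, 1 = case)")
        bad = set(self.folds) - {TRAIN, TEST}
        if bad:
            raise SchemaError(f"unknown fold values: {sorted(bad)}")
        non_numeric = [c for c in self.features.columns
                       if not np.issubdtype(self.features[c].dtype, np.number)]
        if non_numeric:
            raise SchemaError(f"non-numeric feature columns: {non_numeric}")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def X(self) -> np.ndarray:
        """Feature matrix as a float ndarray (samples x features)."""
        return self.features.to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return FeatureTable(
            features=self.features.iloc[idx],
            labels=self.labels[idx],
            folds=self.folds[idx],
            sample_ids=self.sample_ids[idx],
        )

    def train(self) -> "FeatureTable":
        return self.subset(self.folds == TRAIN)

    def test(self) -> "FeatureTable":
        return self.subset(self.folds == TEST)

    def controls(self) -> "FeatureTable":
        return self.subset(self.labels == 0)

    def cases(self) -> "FeatureTable":
        return self.subset(self.labels == 1)

    # -- IO ----------------------------------------------------------------
    def to_frame(self, radius: np.ndarray | None = None) -> pd.DataFrame:
        """Assemble the canonical CSV layout: reserved columns first."""
        out = pd.DataFrame({
            "sample_id": self.sample_ids,
            "label": self.labels,
            "fold": self.folds,
        })
        if radius is not None:
            out["radius"] = np.asarray(radius, dtype=float)
        return pd.concat([out, self.features.reset_index(drop=True)], axis=1)

    def to_csv(self, path: str | Path, radius: np.ndarray | None = None) -> None:
        self.to_frame(radius=radius).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        for col in ("sample_id", "label", "fold"):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} missing")
        feature_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
        return cls(
            features=df[feature_cols],
            labels=df["label"].to_numpy(),
            folds=df["fold"].to_numpy(),
            sample_ids=df["sample_id"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))
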