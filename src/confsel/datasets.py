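"""Labeled descriptor tables: CSV I/O and seeded train/test splitting.

The on-disk format is a plain CSV with a header row: an optional id column,
the numeric descriptor columns in their original order, and a binary label
column (default name ``active_binding``) last.  All descriptor values must be
finite; labels must be exactly 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from confsel.exceptions import (
    DatasetFileError,
    EmptyDatasetError,
    LabelDomainError,
    MissingLabelColumnError,
    NonNumericFeatureError,
    SplitError,
)

DEFAULT_LABEL_COLUMN = "active_binding"
DEFAULT_ID_COLUMN = "sample_id"


@dataclass
class LabeledDataset:
    """A descriptor matrix with binary labels.

    Attributes
    ----------
    features : (n, d) float array of finite descriptor values.
    labels : (n,) int array over {0, 1}; 1 means "active binding".
    feature_names : list of d column names.
    sample_ids : list of n row identifiers (strings or ints).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features.reshape(-1, 1)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.features.shape
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        if not self.sample_ids:
            self.sample_ids = list(range(n))
        if self.labels.shape != (n,):
            raise ValueError(
                f"labels length {self.labels.shape} != number of rows {n}"
            )
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length mismatch")
        if not np.all(np.isfinite(self.features)):
            raise NonNumericFeatureError("non-finite descriptor value")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise LabelDomainError(f"labels outside {{0,1}}: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[int, int]:
        """Counts of each label value, always keyed by both 0 and 1."""
        return {
            0: int(np.sum(self.labels == 0)),
            1: int(np.sum(self.labels == 1)),
        }

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        """Row-subset view (copies) preserving feature names."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            features=self.features[idx].copy(),
            labels=self.labels[idx].copy(),
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass(frozen=True)
class SplitResult:
    """A train/test partition of a :class:`LabeledDataset`."""

    train: LabeledDataset
    test: LabeledDataset
    fraction: float
    seed: int


def load_dataset(
    path: str | Path,
    label_column: str = DEFAULT_LABEL_COLUMN,
    id_column: str | None = None,
) -> LabeledDataset:
    """Read a labeled descriptor table from CSV.

    Parameters
    ----------
    path : CSV file with a header row.
    label_column : name of the binary label column.
    id_column : optional id column; when absent, row indices are used.

    Raises
    ------
    DatasetFileError, MissingLabelColumnError, NonNumericFeatureError,
    LabelDomainError, EmptyDatasetError
    """
    path = Path(path)
    if not path.exists():
        raise DatasetFileError(f"no such file: {path}")
    try:
        # round_trip parser: exact float64 recovery of %.17g-written values
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"empty file: {path}") from exc
    if frame.shape[0] == 0:
        raise EmptyDatasetError(f"no data rows in {path}")
    if label_column not in frame.columns:
        raise MissingLabelColumnError(
            f"label column {label_column!r} not in {list(frame.columns)}"
        )
    labels_raw = frame[label_column]
    labels_num = pd.to_numeric(labels_raw, errors="coerce")
    if labels_num.isna().any() or not set(labels_num.unique()) <= {0, 1}:
        raise LabelDomainError(
            f"label column {label_column!r} contains values outside {{0,1}}"
        )
    sample_ids: list
    if id_column is not None:
        if id_column not in frame.columns:
            raise DatasetFileError(f"id column {id_column!r} not found")
        sample_ids = frame[id_column].tolist()
        frame = frame.drop(columns=[id_column])
    elif DEFAULT_ID_COLUMN in frame.columns:
        sample_ids = frame[DEFAULT_ID_COLUMN].tolist()
        frame = frame.drop(columns=[DEFAULT_ID_COLUMN])
    else:
        sample_ids = list(range(frame.shape[0]))
    feature_frame = frame.drop(columns=[label_column])
    # provenance column written by resampling is metadata, not a feature
    if "provenance" in feature_frame.columns:
        feature_frame = feature_frame.drop(columns=["provenance"])
    numeric = feature_frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad_cols = numeric.columns[numeric.isna().any()].tolist()
        raise NonNumericFeatureError(
            f"non-numeric descriptor cell(s) in columns {bad_cols}"
        )
    values = numeric.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise NonNumericFeatureError("non-finite descriptor value in file")
    return LabeledDataset(
        features=values,
        labels=labels_num.to_numpy(dtype=int),
        feature_names=list(feature_frame.columns),
        sample_ids=sample_ids,
    )


def write_dataset(
    data: LabeledDataset,
    path: str | Path,
    label_column: str = DEFAULT_LABEL_COLUMN,
    provenance: list[str] | None = None,
) -> Path:
    """Write a dataset as CSV: ids, features (input order), label last.

    ``provenance``, when given, adds a per-row "original"/"smote" column
    between the features and the label.
    """
    path = Path(path)
    frame = pd.DataFrame(data.features, columns=data.feature_names)
    frame.insert(0, DEFAULT_ID_COLUMN, data.sample_ids)
    if provenance is not None:
        if len(provenance) != data.n_samples:
            raise ValueError("provenance length mismatch")
        frame["provenance"] = provenance
    frame[label_column] = data.labels
    # %.17g guarantees float64 round-trips exactly through the CSV
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def random_split(
    data: LabeledDataset,
    fraction: float,
    seed: int,
    stratified: bool = False,
) -> SplitResult:
    """Randomly partition ``data`` into train/test without replacement.

    Train size is ``floor(fraction * n)``.  Sampling is simple (non-
    stratified) by default; set ``stratified=True`` to sample each class
    proportionally instead.  Reproducible for a fixed seed.
    """
    n = data.n_samples
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must lie in (0,1), got {fraction}")
    n_train = math.floor(fraction * n)
    if n_train < 1 or n - n_train < 1:
        raise SplitError(
            f"degenerate split: n={n}, fraction={fraction} "
            f"gives train={n_train}, test={n - n_train}"
        )
    rng = np.random.default_rng(seed)
    if stratified:
        train_idx_parts = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(data.labels == cls)
            k = round(fraction * cls_idx.size)
            train_idx_parts.append(
                rng.choice(cls_idx, size=k, replace=False)
            )
        train_idx = np.sort(np.concatenate(train_idx_parts))
    else:
        train_idx = np.sort(rng.choice(n, size=n_train, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    test_idx = np.flatnonzero(~mask)
    return SplitResult(
        train=data.subset(train_idx),
        test=data.subset(test_idx),
        fraction=fraction,
        seed=seed,
    )
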