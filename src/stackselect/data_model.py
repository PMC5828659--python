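"""Dataset container, delimited-file I/O and stratified train/test splitting.

A :class:`Dataset` is the in-memory currency of the package: a dense numeric
samples × features matrix, a categorical label vector, feature names and the
sorted list of class labels.  Labels are kept as strings; integer class codes
are assigned by sorted label order so the coding is reproducible regardless
of file row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset", "SplitDataset", "read_table", "write_table", "stratified_split"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class Dataset:
    """Labeled expression matrix.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Numeric feature matrix (expression values or binary clinical features).
    y : ndarray of shape (n_samples,)
        Class label per sample, stored as strings.
    feature_names : list of str
        Column names, unique, one per feature.
    class_names : list of str
        Sorted distinct class labels; class code = index in this list.
    sample_ids : ndarray of shape (n_samples,)
        Row identities (source-file row indices by default); used to verify
        that splits partition the input.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    class_names: list[str] = field(default=None)  # type: ignore[assignment]
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValidationError("X must be a 2-D samples × features matrix")
        self.y = np.asarray([str(v) for v in np.asarray(self.y).ravel()], dtype=object)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError(
                f"row count of X ({self.X.shape[0]}) != length of y ({self.y.shape[0]})"
            )
        self.feature_names = [str(n) for n in self.feature_names]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("duplicate feature names")
        observed = sorted(set(self.y))
        if self.class_names is None:
            self.class_names = observed
        else:
            self.class_names = [str(c) for c in self.class_names]
            missing = set(observed) - set(self.class_names)
            if missing:
                raise ValidationError(f"labels {sorted(missing)} absent from class_names")
        if len(self.class_names) < 2:
            raise ValidationError(
                f"need at least 2 classes, found {len(self.class_names)}: {self.class_names}"
            )
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.X.shape[0])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape[0] != self.X.shape[0]:
                raise ValidationError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def y_codes(self) -> np.ndarray:
        """Integer class codes by sorted label order."""
        lookup = {c: i for i, c in enumerate(self.class_names)}
        return np.asarray([lookup[v] for v in self.y], dtype=np.int64)

    def subset_rows(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            class_names=list(self.class_names),
            sample_ids=self.sample_ids[idx],
        )

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.y == c)) for c in self.class_names}


@dataclass
class SplitDataset:
    """A stratified train/test partition of one :class:`Dataset`."""

    train: Dataset
    test: Dataset

    def __post_init__(self) -> None:
        if self.train.feature_names != self.test.feature_names:
            raise ValidationError("train/test feature_names differ")
        if self.train.class_names != self.test.class_names:
            raise ValidationError("train/test class_names differ")
        overlap = set(self.train.sample_ids.tolist()) & set(self.test.sample_ids.tolist())
        if overlap:
            raise ValidationError(f"train/test sample sets overlap: {sorted(overlap)[:5]}")

    @classmethod
    def from_presplit(cls, train: Dataset, test: Dataset) -> "SplitDataset":
        """Pair independently loaded train/test tables.

        Each file carries its own 0-based row indices, so the test ids are
        offset past the train ids to keep sample identities disjoint.
        """
        shifted = Dataset(
            X=test.X,
            y=test.y,
            feature_names=list(test.feature_names),
            class_names=sorted(set(train.class_names) | set(test.class_names)),
            sample_ids=test.sample_ids + train.n_samples,
        )
        train = Dataset(
            X=train.X,
            y=train.y,
            feature_names=list(train.feature_names),
            class_names=list(shifted.class_names),
            sample_ids=train.sample_ids,
        )
        return cls(train=train, test=shifted)


def read_table(path, label_column="label", delimiter: str = ",") -> Dataset:
    """Read a delimited samples × features table with one label column.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row.
    label_column : str or int
        Name, or 0-based positional index, of the class-label column.
    delimiter : str
        Field separator.

    Returns
    -------
    Dataset
        Feature column order follows file order minus the label column.
    """
    df = pd.read_csv(path, sep=delimiter, header=0, float_precision="round_trip")
    if isinstance(label_column, int):
        if not 0 <= label_column < df.shape[1]:
            raise ValidationError(
                f"label column index {label_column} out of range for {df.shape[1]} columns"
            )
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValidationError(f"label column {label_column!r} not in header: {list(df.columns)}")
        label_name = label_column
    y = df[label_name].astype(str).to_numpy()
    feats = df.drop(columns=[label_name])
    for col in feats.columns:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        bad = coerced.isna() & feats[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric value {feats[col].iloc[row]!r} at row {row}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValidationError(f"missing value at row {row}, column {col!r}")
        feats[col] = coerced
    return Dataset(
        X=feats.to_numpy(dtype=np.float64),
        y=y,
        feature_names=[str(c) for c in feats.columns],
    )


def write_table(data: Dataset, path, label_column: str = "label", delimiter: str = ",") -> None:
    """Write a Dataset back to the same delimited dialect ``read_table`` accepts.

    Feature values are rendered with ``repr`` round-trip precision so that
    write → read reproduces X bit-exactly.
    """
    df = pd.DataFrame(data.X, columns=data.feature_names)
    # render with repr round-trip precision for a bit-exact write -> read cycle
    df = df.apply(lambda col: col.map(lambda v: repr(float(v))))
    df.insert(0, label_column, data.y)
    df.to_csv(path, sep=delimiter, index=False)


def stratified_split(data: Dataset, train_fraction: float, seed: int) -> SplitDataset:
    """Split into train/test keeping per-class proportions.

    Per class ``c`` the train set receives ``round_half_up(train_fraction *
    count(c))`` samples, the remainder going to test.  The assignment within
    a class is random (seeded); the output preserves original row order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError(f"train_fraction must be in (0,1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in data.class_names:
        idx = np.flatnonzero(data.y == c)
        if idx.size < 2:
            raise ValidationError(f"class {c!r} has {idx.size} sample(s); need >= 2")
        n_train = int(math.floor(train_fraction * idx.size + 0.5))  # round half up
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides non-empty per class
        perm = rng.permutation(idx.size)
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    train_idx_a = np.sort(np.asarray(train_idx, dtype=np.int64))
    test_idx_a = np.sort(np.asarray(test_idx, dtype=np.int64))
    return SplitDataset(train=data.subset_rows(train_idx_a), test=data.subset_rows(test_idx_a))
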