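"""Dimensionality reduction before the multiobjective search.

Two filter paths are provided, matching common practice for expression data:

* **χ² attribute ranking** — each feature is discretized into equal-frequency
  bins and scored by the χ² test of independence between bin membership and
  the class label (no continuity correction); the top-k features are kept.
* **per-sample normalization + SNR filtering** — each sample (row) is scaled
  to mean 0 / variance 1, then each feature is scored with the Golub
  signal-to-noise statistic SNR = (μ₁−μ₂)/(σ₁+σ₂) over the two classes and
  features with |SNR| at or above the mean absolute SNR are retained.

Both scorers are fit on the training split only in the pipeline, to avoid
leaking test-label information into feature selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data_model import Dataset, ValidationError

__all__ = ["FeatureScoreTable", "chi2_top_k", "normalize_samples", "snr_filter", "apply_selection"]


@dataclass
class FeatureScoreTable:
    """Per-feature scores plus the boolean selection mask they induce."""

    feature_names: list[str]
    scores: np.ndarray
    selected: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.selected = np.asarray(self.selected, dtype=bool)
        if not (len(self.feature_names) == self.scores.size == self.selected.size):
            raise ValidationError("feature_names, scores and selected must have equal length")

    @property
    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]

    def ranking(self) -> list[tuple[str, float]]:
        """Selected features in descending score order (|score| for SNR)."""
        key = np.abs(self.scores) if self.method == "snr" else self.scores
        order = np.lexsort((np.arange(len(self.feature_names)), -key))
        return [(self.feature_names[i], float(self.scores[i])) for i in order if self.selected[i]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "score": self.scores, "selected": self.selected}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _discretize(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization; low-cardinality features pass through."""
    if np.unique(x).size <= n_bins:
        _, codes = np.unique(x, return_inverse=True)
        return codes
    codes = pd.qcut(x, q=n_bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=np.int64)


def _chi2_statistic(x_codes: np.ndarray, y: np.ndarray) -> float:
    table = pd.crosstab(x_codes, y).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0  # constant feature (or class) carries no association
    stat, _, _, _ = chi2_contingency(table, correction=False)
    return float(stat)


def chi2_top_k(data: Dataset, k: int, n_bins: int = 10) -> FeatureScoreTable:
    """Rank features by χ² independence from the class label; keep the k best.

    Continuous features are discretized into ``n_bins`` equal-frequency bins
    first.  Ties in the ranking are broken by ascending feature index.

    Raises
    ------
    ValidationError
        If ``k`` exceeds the number of features.
    """
    if k < 1:
        raise ValidationError(f"k must be positive, got {k}")
    if k > data.n_features:
        raise ValidationError(f"k={k} exceeds n_features={data.n_features}")
    if n_bins < 1:
        raise ValidationError(f"n_bins must be positive, got {n_bins}")
    scores = np.empty(data.n_features)
    for j in range(data.n_features):
        scores[j] = _chi2_statistic(_discretize(data.X[:, j], n_bins), data.y)
    # top-k, ties by ascending feature index
    order = np.lexsort((np.arange(data.n_features), -scores))
    selected = np.zeros(data.n_features, dtype=bool)
    selected[order[:k]] = True
    return FeatureScoreTable(list(data.feature_names), scores, selected, method="chi2")


def normalize_samples(data: Dataset) -> Dataset:
    """Scale every sample (row) to mean 0 and variance 1.

    Uses the population variance (ddof=0) so a normalized row has exactly
    unit mean square deviation; the transform is idempotent.
    """
    means = data.X.mean(axis=1, keepdims=True)
    sds = data.X.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sds.ravel() == 0.0)
    if flat.size:
        raise ValidationError(
            f"sample {data.sample_ids[flat[0]]} is constant and cannot be normalized"
        )
    return Dataset(
        X=(data.X - means) / sds,
        y=data.y,
        feature_names=list(data.feature_names),
        class_names=list(data.class_names),
        sample_ids=data.sample_ids,
    )


def snr_filter(data: Dataset) -> FeatureScoreTable:
    """Golub signal-to-noise ranking with mean-absolute-SNR thresholding.

    Per feature, SNR = (μ₁−μ₂)/(σ₁+σ₂) where μ and σ are the per-class mean
    and sample standard deviation (ddof=1).  Features whose |SNR| is at least
    the mean of all |SNR| values are selected.  Only defined for two classes.
    """
    if len(data.class_names) != 2:
        raise ValidationError(
            f"SNR filtering needs exactly 2 classes, got {len(data.class_names)}"
        )
    c1, c2 = data.class_names
    m1 = data.y == c1
    m2 = data.y == c2
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError("each class needs >= 2 samples for SNR")
    mu1 = data.X[m1].mean(axis=0)
    mu2 = data.X[m2].mean(axis=0)
    sd1 = data.X[m1].std(axis=0, ddof=1)
    sd2 = data.X[m2].std(axis=0, ddof=1)
    denom = sd1 + sd2
    zero = denom == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature(s) with zero within-class spread; SNR set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    snr = np.zeros(data.n_features)
    np.divide(mu1 - mu2, denom, out=snr, where=~zero)
    threshold = np.abs(snr).mean()
    selected = np.abs(snr) >= threshold
    return FeatureScoreTable(list(data.feature_names), snr, selected, method="snr")


def apply_selection(data: Dataset, table: FeatureScoreTable) -> Dataset:
    """Project a dataset onto the features a score table selected."""
    if table.feature_names != data.feature_names:
        raise ValidationError("score table was computed on different features")
    keep = np.flatnonzero(table.selected)
    return Dataset(
        X=data.X[:, keep],
        y=data.y,
        feature_names=[data.feature_names[i] for i in keep],
        class_names=list(data.class_names),
        sample_ids=data.sample_ids,
    )
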