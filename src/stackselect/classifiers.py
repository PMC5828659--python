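"""Base-learner registry and leave-one-out objective evaluation.

Four candidate learners are searched over, each identified by an integer
code and a small hyperparameter grid:

====  ====================================  =========================================
code  learner                               grid
====  ====================================  =========================================
1     random forest (RF)                    n_trees ∈ {10, 20, 30}; n_rand_features ∈ {0, 5, 6}
2     random tree (RT)                      min_leaf_weight ∈ {1.0, 1.05, 1.25}; n_rand_features ∈ {0, 3, 7}
3     SMO (linear-kernel SVM)               complexity C ∈ {1, 3, 8}
4     logistic regression (LR)              (defaults)
====  ====================================  =========================================

``n_rand_features = 0`` means "use the default heuristic count of candidate
features per split", int(log2(m)) + 1 for m available features — the
convention of classic decision-forest implementations.  The random tree's
"minimum total weight of instances in a leaf" maps to a minimum
samples-per-leaf constraint with fractional weights rounded up.

A candidate is scored by leave-one-out cross-validation: the model is
refitted n times, each time predicting the single held-out sample; the
pooled (truth, prediction) pairs give macro-averaged precision and recall,
and the third objective is the size of the feature subset in play.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_score, recall_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import Dataset, ValidationError

__all__ = [
    "PARAM_GRIDS",
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "EvalResult",
    "build_classifier",
    "loocv_predictions",
    "loocv_evaluate",
    "derive_seed",
]

#: hyperparameter grid per classifier code; one tuple of allowed values per slot
PARAM_GRIDS: dict[int, tuple[tuple, ...]] = {
    1: ((10, 20, 30), (0, 5, 6)),
    2: ((1.0, 1.05, 1.25), (0, 3, 7)),
    3: ((1, 3, 8),),
    4: (),
}

CLASSIFIER_NAMES = {1: "RF", 2: "RT", 3: "SMO", 4: "LR"}


def derive_seed(seed: int, *tags: int) -> int:
    """Deterministically derive a child seed below 2**31 from a root seed."""
    state = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(t) & 0x7FFFFFFF for t in tags]])
    return int(state.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ClassifierSpec:
    """One point in the classifier × hyperparameter search space."""

    code: int
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.code not in PARAM_GRIDS:
            raise ValidationError(f"unknown classifier code {self.code}; expected 1-4")
        object.__setattr__(self, "params", tuple(self.params))
        grid = PARAM_GRIDS[self.code]
        if len(self.params) != len(grid):
            raise ValidationError(
                f"{CLASSIFIER_NAMES[self.code]} takes {len(grid)} parameter(s), "
                f"got {len(self.params)}"
            )
        for slot, (value, allowed) in enumerate(zip(self.params, grid)):
            if value not in allowed:
                raise ValidationError(
                    f"{CLASSIFIER_NAMES[self.code]} slot {slot}: {value} not in {allowed}"
                )

    @property
    def name(self) -> str:
        return CLASSIFIER_NAMES[self.code]

    def to_json(self) -> dict:
        return {"code": self.code, "params": list(self.params)}

    @classmethod
    def from_json(cls, obj: dict) -> "ClassifierSpec":
        return cls(code=int(obj["code"]), params=tuple(obj["params"]))


@dataclass(frozen=True)
class EvalResult:
    """The three objective values of one candidate, plus their F-measure."""

    precision: float
    recall: float
    n_features: int
    f_measure: float = field(init=False)

    def __post_init__(self) -> None:
        p, r = self.precision, self.recall
        f = 0.0 if (p + r) == 0 else 2.0 * p * r / (p + r)
        object.__setattr__(self, "f_measure", f)

    def to_json(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "n_features": self.n_features,
            "f_measure": self.f_measure,
        }


def _max_features(n_rand: int, m: int) -> int:
    if n_rand == 0:
        return max(1, int(math.log2(m)) + 1) if m > 1 else 1
    return min(n_rand, m)


def build_classifier(spec: ClassifierSpec, seed: int) -> Callable[[int], BaseEstimator]:
    """Return a factory mapping the number of active features to an estimator.

    The factory indirection exists because the per-split feature-subsample
    size depends on how many features the chromosome's mask keeps.
    """
    if spec.code == 1:
        n_trees, n_rand = spec.params

        def factory(m: int) -> BaseEstimator:
            return RandomForestClassifier(
                n_estimators=int(n_trees),
                max_features=_max_features(int(n_rand), m),
                random_state=seed,
                n_jobs=1,
            )

    elif spec.code == 2:
        min_weight, n_rand = spec.params
        min_leaf = int(math.ceil(float(min_weight)))

        def factory(m: int) -> BaseEstimator:
            return DecisionTreeClassifier(
                min_samples_leaf=min_leaf,
                max_features=_max_features(int(n_rand), m),
                random_state=seed,
            )

    elif spec.code == 3:
        (complexity,) = spec.params

        def factory(m: int) -> BaseEstimator:
            return SVC(kernel="linear", C=float(complexity), random_state=seed)

    else:  # LR, defaults

        def factory(m: int) -> BaseEstimator:
            return LogisticRegression(max_iter=1000, random_state=seed)

    return factory


def loocv_predictions(
    factory: Callable[[int], BaseEstimator],
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Pooled leave-one-out predictions for an arbitrary estimator factory.

    Each fold refits a fresh estimator seeded from ``(seed, fold)`` so runs
    are reproducible without all folds sharing one stream.
    """
    n = X.shape[0]
    if n < 3:
        raise ValidationError(f"LOOCV needs >= 3 samples, got {n}")
    preds = np.empty(n, dtype=np.asarray(y).dtype)
    all_idx = np.arange(n)
    for i in range(n):
        rest = all_idx[all_idx != i]
        model = factory(X.shape[1])
        if hasattr(model, "random_state"):
            model.random_state = derive_seed(seed, i)
        model.fit(X[rest], y[rest])
        preds[i] = model.predict(X[i : i + 1])[0]
    return preds


def loocv_evaluate(
    spec: ClassifierSpec,
    data: Dataset,
    feature_mask: Sequence[bool] | np.ndarray,
    seed: int,
) -> EvalResult:
    """Score a (classifier, hyperparameters, feature subset) candidate.

    Macro-averaged precision and recall over the pooled LOOCV predictions;
    a class that is never predicted contributes precision 0 rather than NaN,
    keeping the objectives total.
    """
    mask = np.asarray(feature_mask, dtype=bool)
    if mask.size != data.n_features:
        raise ValidationError(
            f"mask length {mask.size} != n_features {data.n_features}"
        )
    k = int(mask.sum())
    if k == 0:
        raise ValidationError("empty feature mask; caller must repair before evaluating")
    factory = build_classifier(spec, seed)
    y = data.y_codes
    preds = loocv_predictions(factory, data.X[:, mask], y, seed)
    labels = np.arange(len(data.class_names))
    prec = precision_score(y, preds, labels=labels, average="macro", zero_division=0)
    rec = recall_score(y, preds, labels=labels, average="macro", zero_division=0)
    return EvalResult(precision=float(prec), recall=float(rec), n_features=k)
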