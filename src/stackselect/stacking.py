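"""Stage 2: stacked ensemble over the unique rank-1 solutions.

Every unique rank-1 solution from the stage-1 search is refit on the
training split (restricted to its own feature mask) and its predicted class
codes are appended to the feature matrix as new columns P_1..P_N — for the
training and the test set alike, always using the train-fitted base models.
The meta-learner is the base solution with the highest stage-1 F-measure,
retrained on the augmented training matrix; its accuracy on the augmented
test set is the final accuracy of the combined solution.

For more than two classes the meta level is decomposed one-vs-rest: one
binary meta-model per class (that class coded 1, the rest 0), the predicted
label being the class whose model yields the highest positive score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .classifiers import ClassifierSpec, EvalResult, build_classifier, derive_seed
from .data_model import Dataset, SplitDataset, ValidationError
from .moo_search import Chromosome, ParetoFront, unique_rank1

__all__ = ["StackedModel", "binarize_labels", "augment", "fit_stack"]


def binarize_labels(y: np.ndarray, positive_class: str, class_names: list[str] | None = None) -> np.ndarray:
    """0/1 encoding of a label vector: 1 = positive class, 0 = the rest."""
    y = np.asarray([str(v) for v in y], dtype=object)
    known = set(class_names) if class_names is not None else set(y)
    if positive_class not in known:
        raise ValidationError(f"positive class {positive_class!r} not among {sorted(known)}")
    return (y == positive_class).astype(np.int64)


@dataclass
class StackedModel:
    """Fitted stage-2 ensemble.

    ``meta_models`` holds one estimator for binary problems and one per class
    (in class-code order) for one-vs-rest multiclass problems.
    """

    base_solutions: list[tuple[ClassifierSpec, np.ndarray]]
    base_models: list[BaseEstimator]
    meta_spec: ClassifierSpec
    meta_models: list[BaseEstimator]
    augmented_feature_names: list[str]
    class_names: list[str]
    meta_features: str = "all"

    @property
    def n_bases(self) -> int:
        return len(self.base_solutions)

    @property
    def is_one_vs_rest(self) -> bool:
        return len(self.meta_models) > 1

    def predict(self, data: Dataset) -> np.ndarray:
        """Predicted class codes for new samples (original feature space)."""
        aug = augment(data, self.base_solutions, self.base_models)
        Z = _meta_matrix(aug.X, data.n_features, self.n_bases, self.meta_features,
                         self.base_solutions)
        if not self.is_one_vs_rest:
            return np.asarray(self.meta_models[0].predict(Z), dtype=np.int64)
        scores = np.column_stack([_positive_score(m, Z) for m in self.meta_models])
        return np.asarray(np.argmax(scores, axis=1), dtype=np.int64)  # ties -> lowest code


def _positive_score(model: BaseEstimator, Z: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(Z), dtype=np.float64)
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(Z)
        if proba.shape[1] == 1:  # single class seen during fit
            return np.full(Z.shape[0], float(model.classes_[0]))
        return np.asarray(proba[:, list(model.classes_).index(1)], dtype=np.float64)
    return np.asarray(model.predict(Z), dtype=np.float64)  # hard labels as scores


def augment(
    data: Dataset,
    base_solutions: list[tuple[ClassifierSpec, np.ndarray]],
    trained_bases: list[BaseEstimator],
) -> Dataset:
    """Append one prediction column per base solution to the feature matrix.

    Column P_j holds base j's predicted class code for each sample; original
    columns are unchanged.  The trained bases must have been fit on the
    training split only, so the same call is valid for train and test data.
    """
    if len(base_solutions) != len(trained_bases):
        raise ValidationError("base_solutions and trained_bases length mismatch")
    cols = []
    for (spec, mask), model in zip(base_solutions, trained_bases):
        mask = np.asarray(mask, dtype=bool)
        if mask.size != data.n_features:
            raise ValidationError(
                f"base mask length {mask.size} != dataset width {data.n_features}"
            )
        cols.append(np.asarray(model.predict(data.X[:, mask]), dtype=np.float64))
    pred_names = [f"P_{j + 1}" for j in range(len(cols))]
    return Dataset(
        X=np.column_stack([data.X] + cols) if cols else data.X.copy(),
        y=data.y,
        feature_names=list(data.feature_names) + pred_names,
        class_names=list(data.class_names),
        sample_ids=data.sample_ids,
    )


def _meta_matrix(
    aug_X: np.ndarray,
    n_original: int,
    n_bases: int,
    meta_features: str,
    base_solutions: list[tuple[ClassifierSpec, np.ndarray]],
) -> np.ndarray:
    if meta_features == "all":
        return aug_X
    if meta_features == "preds-only":
        return aug_X[:, n_original:]
    if meta_features == "mask+preds":
        best_mask = np.asarray(base_solutions[0][1], dtype=bool)
        keep = np.concatenate([np.flatnonzero(best_mask), np.arange(n_original, n_original + n_bases)])
        return aug_X[:, keep]
    raise ValidationError(f"unknown meta_features mode {meta_features!r}")


def fit_stack(
    front: ParetoFront,
    split: SplitDataset,
    seed: int,
    meta_features: str = "all",
) -> tuple[StackedModel, float]:
    """Fit the stage-2 stacked ensemble and return (model, test accuracy).

    Bases are the unique rank-1 solutions; the meta-learner is the base with
    the highest stage-1 F-measure, trained on the augmented training set.
    Binary problems use a single meta-model; k > 2 classes get one
    one-vs-rest meta-model per class, fused by highest positive score with
    ties resolved to the lowest class code.
    """
    bases = unique_rank1(front)  # raises on empty front / empty rank 1
    base_solutions = [(chrom.spec, chrom.feature_mask.copy()) for chrom, _ in bases]
    train, test = split.train, split.test
    y_train = train.y_codes

    base_models: list[BaseEstimator] = []
    for j, (spec, mask) in enumerate(base_solutions):
        model = build_classifier(spec, derive_seed(seed, 10, j))(int(mask.sum()))
        model.fit(train.X[:, mask], y_train)
        base_models.append(model)

    aug_train = augment(train, base_solutions, base_models)
    aug_test = augment(test, base_solutions, base_models)
    n_bases = len(base_solutions)
    Z_train = _meta_matrix(aug_train.X, train.n_features, n_bases, meta_features, base_solutions)
    Z_test = _meta_matrix(aug_test.X, test.n_features, n_bases, meta_features, base_solutions)

    meta_spec = base_solutions[0][0]  # highest stage-1 F-measure
    n_classes = len(train.class_names)
    meta_models: list[BaseEstimator] = []
    if n_classes == 2:
        meta = build_classifier(meta_spec, derive_seed(seed, 20))(Z_train.shape[1])
        meta.fit(Z_train, y_train)
        meta_models.append(meta)
        preds = np.asarray(meta.predict(Z_test), dtype=np.int64)
    else:
        for c in range(n_classes):
            meta = build_classifier(meta_spec, derive_seed(seed, 20, c))(Z_train.shape[1])
            meta.fit(Z_train, (y_train == c).astype(np.int64))
            meta_models.append(meta)
        scores = np.column_stack([_positive_score(m, Z_test) for m in meta_models])
        preds = np.asarray(np.argmax(scores, axis=1), dtype=np.int64)

    accuracy = float(np.mean(preds == test.y_codes))
    model = StackedModel(
        base_solutions=base_solutions,
        base_models=base_models,
        meta_spec=meta_spec,
        meta_models=meta_models,
        augmented_feature_names=list(aug_train.feature_names),
        class_names=list(train.class_names),
        meta_features=meta_features,
    )
    return model, accuracy
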