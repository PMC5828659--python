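"""End-to-end orchestration: split → preprocess → stage 1 → stage 2 → report.

The pipeline is a pure function of (input data, configuration, seed): the
single global seed fans out to per-stage child seeds through a fixed
derivation, so each stage is individually reproducible and two runs with
the same configuration produce byte-identical ``front.json`` and
``report.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .classifiers import derive_seed
from .data_model import Dataset, SplitDataset, ValidationError, read_table, stratified_split
from .moo_search import ParetoFront, run_nsga2, unique_rank1
from .preprocess import apply_selection, chi2_top_k, normalize_samples, snr_filter
from .stacking import fit_stack
from .synth import SynthConfig, generate

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# fixed stage tags for seed fan-out
_SEED_SPLIT, _SEED_STAGE1, _SEED_STAGE2 = 101, 102, 103


@dataclass
class RunConfig:
    """All pipeline knobs; defaults follow the published study conditions
    (population 52, 50 generations, crossover 0.9, mutation 0.1, 60/40 split)."""

    data: str | None = None  # CSV/TSV path; None -> synthetic data
    test_data: str | None = None  # optional pre-split test file
    label_column: str | int = "label"
    delimiter: str = ","
    train_fraction: float = 0.6
    preprocess: str = "none"  # {chi2, snr, none}
    top_k: int = 100
    n_bins: int = 10
    fit_on: str = "train"  # {train, all}
    pop_size: int = 52
    n_generations: int = 50
    p_cross: float = 0.9
    p_mut: float = 0.1
    meta_features: str = "all"
    seed: int = 0
    out_dir: str = "stackselect_out"
    synth: dict = field(default_factory=dict)  # SynthConfig overrides when data is None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _load_split(cfg: RunConfig) -> SplitDataset:
    if cfg.data is None:
        synth_cfg = SynthConfig(**{"seed": derive_seed(cfg.seed, 100), **cfg.synth})
        data = generate(synth_cfg)
        logger.info("generated synthetic dataset: %d samples x %d features",
                    data.n_samples, data.n_features)
        return stratified_split(data, cfg.train_fraction, derive_seed(cfg.seed, _SEED_SPLIT))
    data = read_table(cfg.data, cfg.label_column, cfg.delimiter)
    if cfg.test_data is not None:
        test = read_table(cfg.test_data, cfg.label_column, cfg.delimiter)
        return SplitDataset.from_presplit(data, test)
    return stratified_split(data, cfg.train_fraction, derive_seed(cfg.seed, _SEED_SPLIT))


def _preprocess(split: SplitDataset, cfg: RunConfig) -> tuple[SplitDataset, list[str]]:
    if cfg.preprocess == "none":
        return split, list(split.train.feature_names)
    if cfg.fit_on == "all":
        # escape hatch: score on the full data (train ∪ test), then project both
        import numpy as np

        full = Dataset(
            X=np.vstack([split.train.X, split.test.X]),
            y=np.concatenate([split.train.y, split.test.y]),
            feature_names=list(split.train.feature_names),
            class_names=list(split.train.class_names),
        )
        fit_data = full
    else:
        fit_data = split.train
    train, test = split.train, split.test
    if cfg.preprocess == "chi2":
        table = chi2_top_k(fit_data, k=min(cfg.top_k, fit_data.n_features), n_bins=cfg.n_bins)
    elif cfg.preprocess == "snr":
        train = normalize_samples(train)
        test = normalize_samples(test)
        fit_norm = normalize_samples(fit_data) if cfg.fit_on == "all" else train
        table = snr_filter(fit_norm)
    else:
        raise ValidationError(f"unknown preprocess method {cfg.preprocess!r}")
    new_split = SplitDataset(
        train=apply_selection(train, table), test=apply_selection(test, table)
    )
    logger.info("preprocess=%s kept %d / %d features",
                cfg.preprocess, new_split.train.n_features, split.train.n_features)
    return new_split, table.selected_names


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full two-stage pipeline; write front.json, report.json and a log.

    Returns the report dictionary (also written to ``out_dir/report.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("stackselect")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        split = _load_split(cfg)
        split, selected_names = _preprocess(split, cfg)

        front = run_nsga2(
            split.train,
            pop_size=cfg.pop_size,
            n_generations=cfg.n_generations,
            p_cross=cfg.p_cross,
            p_mut=cfg.p_mut,
            seed=derive_seed(cfg.seed, _SEED_STAGE1),
        )
        front.save(out / "front.json")

        bases = unique_rank1(front)
        stacked, final_accuracy = fit_stack(
            front, split, seed=derive_seed(cfg.seed, _SEED_STAGE2),
            meta_features=cfg.meta_features,
        )

        # per-base test accuracies, for comparison with the stacked result
        import numpy as np

        base_rows = []
        y_test = split.test.y_codes
        for j, (chrom, res) in enumerate(bases):
            mask = chrom.feature_mask
            model = stacked.base_models[j]  # already fit on the training split
            acc = float(np.mean(model.predict(split.test.X[:, mask]) == y_test))
            base_rows.append(
                {
                    "classifier": chrom.spec.name,
                    "params": list(chrom.spec.params),
                    "n_features": res.n_features,
                    "loocv_precision": res.precision,
                    "loocv_recall": res.recall,
                    "loocv_f_measure": res.f_measure,
                    "test_accuracy": acc,
                    "selected_features": [
                        split.train.feature_names[i] for i in np.flatnonzero(mask)
                    ],
                }
            )

        report = {
            "config": {k: v for k, v in asdict(cfg).items()},
            "n_train": split.train.n_samples,
            "n_test": split.test.n_samples,
            "n_features_after_preprocess": split.train.n_features,
            "preprocess_selected": selected_names if cfg.preprocess != "none" else None,
            "n_unique_solutions": len(bases),
            "bases": base_rows,
            "meta_classifier": stacked.meta_spec.name,
            "meta_params": list(stacked.meta_spec.params),
            "final_accuracy": final_accuracy,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("final stacked test accuracy: %.4f", final_accuracy)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)
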