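"""Synthetic expression-matrix generator.

Emulates the structure the two-stage method assumes: a handful of
informative features whose class-conditional means differ, buried among
many pure-noise features, with Gaussian within-class variation.  Feature
names flag the planted structure (``inf_1``.., ``noise_1``..) so tests can
check that the filters and the search recover it.

Gaussian class-conditional shifts are the minimal structure that both the
SNR statistic and χ² ranking are designed to detect; count-style noise
models (negative binomial) and batch effects are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset, ValidationError

__all__ = ["SynthConfig", "generate", "perfectly_separable"]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    ``effect_size`` is the between-class mean shift in units of the
    within-class standard deviation: informative feature j has mean
    ``c * effect_size`` in class c, noise features have mean 0, and every
    feature has standard deviation ``noise_sd``.
    """

    n_per_class: int = 25
    n_features: int = 100
    n_informative: int = 5
    effect_size: float = 3.0
    n_classes: int = 2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be positive")
        if self.n_features < 1:
            raise ValidationError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValidationError("need 0 <= n_informative <= n_features")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


def generate(config: SynthConfig) -> Dataset:
    """Draw one dataset under the given study conditions (seeded)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_class * config.n_classes
    X = rng.normal(0.0, config.noise_sd, size=(n, config.n_features))
    labels = np.repeat(np.arange(config.n_classes), config.n_per_class)
    for c in range(config.n_classes):
        X[labels == c, : config.n_informative] += c * config.effect_size
    names = [f"inf_{j + 1}" for j in range(config.n_informative)] + [
        f"noise_{j + 1}" for j in range(config.n_features - config.n_informative)
    ]
    y = np.asarray([f"class_{c}" for c in labels], dtype=object)
    return Dataset(X=X, y=y, feature_names=names)


def perfectly_separable(
    n_samples: int = 50, n_features: int = 20, n_classes: int = 2, seed: int = 0
) -> Dataset:
    """Dataset whose first feature equals the class code exactly.

    One noiseless, perfectly informative feature among ``n_features - 1``
    standard-normal noise features; used to test that the search recovers
    the planted optimum (objectives (1, 1, 1)).
    """
    if n_samples % n_classes != 0:
        raise ValidationError("n_samples must divide evenly among classes")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_classes), n_samples // n_classes)
    X = rng.normal(size=(n_samples, n_features))
    X[:, 0] = labels.astype(np.float64)
    names = ["inf_1"] + [f"noise_{j}" for j in range(1, n_features)]
    y = np.asarray([f"class_{c}" for c in labels], dtype=object)
    return Dataset(X=X, y=y, feature_names=names)
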