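import numpy as np
import pytest

import stackselect as ss


@pytest.fixture
def tiny_dataset():
    """4 samples, 3 features, 2 classes — smallest legal container."""
    return ss.Dataset(
        X=np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [5.0, 6.0, 7.0], [6.0, 7.0, 8.0]]),
        y=np.array(["A", "A", "B", "B"]),
        feature_names=["f1", "f2", "f3"],
    )


@pytest.fixture
def balanced_dataset():
    """10 samples (5 per class), 4 features, one of them informative."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 4))
    y = np.array(["neg"] * 5 + ["pos"] * 5)
    X[5:, 0] += 5.0
    return ss.Dataset(X=X, y=y, feature_names=["inf", "n1", "n2", "n3"])


@pytest.fixture(scope="session")
def planted_front():
    """Seeded stage-1 run on data with one perfectly informative feature.

    Session-scoped: several tests inspect the same run (optimum recovery,
    elitism/hypervolume history, dedup behavior) and the search is the
    expensive part of the suite.
    """
    data = ss.perfectly_separable(n_samples=50, n_features=20, seed=7)
    front = ss.run_nsga2(data, pop_size=20, n_generations=15, seed=1)
    return data, front


def random_objectives(rng, n):
    """Random 3-objective vectors shaped like the search's (p, r, k) triples."""
    return [
        ss.ObjectiveVector(
            float(rng.integers(0, 11)) / 10.0,
            float(rng.integers(0, 11)) / 10.0,
            int(rng.integers(1, 8)),
        )
        for _ in range(n)
    ]


def brute_force_ranks(objs):
    """O(n^2 * m) dominance-count oracle: peel non-dominated layers."""
    n = len(objs)
    remaining = set(range(n))
    ranks = [0] * n
    r = 1
    while remaining:
        layer = [
            i
            for i in remaining
            if not any(objs[j].dominates(objs[i]) for j in remaining if j != i)
        ]
        for i in layer:
            ranks[i] = r
        remaining -= set(layer)
        r += 1
    return ranks
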