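"""Stage 1: elitist NSGA-II over (classifier, hyperparameters, feature mask).

Each individual is a three-part chromosome: a classifier code, that
classifier's hyperparameter slot values, and a binary feature-inclusion
mask.  Fitness is the leave-one-out objective triple (macro precision ↑,
macro recall ↑, number of selected features ↓).  The loop is the standard
elitist NSGA-II: binary tournament on (rank, crowding) builds the mating
pool, single-point crossover acts on the feature part only, three mutation
flavors perturb progressively smaller portions of the string, and parents
plus offspring are truncated back to the population size by non-dominated
rank with crowding-distance tie-breaks.

Objective evaluation is cached on (code, params, mask) — LOOCV dominates
runtime and duplicate chromosomes are common late in a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .classifiers import (
    PARAM_GRIDS,
    ClassifierSpec,
    EvalResult,
    derive_seed,
    loocv_evaluate,
)
from .data_model import Dataset, ValidationError

__all__ = [
    "Chromosome",
    "ObjectiveVector",
    "FrontMember",
    "ParetoFront",
    "init_population",
    "random_chromosome",
    "non_dominated_sort",
    "crowding_distance",
    "crossover",
    "mutate",
    "run_nsga2",
    "unique_rank1",
    "hypervolume",
]

logger = logging.getLogger(__name__)


@dataclass
class Chromosome:
    """One candidate solution: classifier spec plus feature mask."""

    spec: ClassifierSpec
    feature_mask: np.ndarray

    def __post_init__(self) -> None:
        self.feature_mask = np.asarray(self.feature_mask, dtype=bool)
        if self.feature_mask.ndim != 1:
            raise ValidationError("feature_mask must be 1-D")
        if not self.feature_mask.any():
            raise ValidationError("feature mask has no bits set; repair before construction")

    def key(self) -> tuple:
        """Dedup/caching identity: (code, params, mask bits)."""
        return (self.spec.code, self.spec.params, self.feature_mask.tobytes())

    def copy(self) -> "Chromosome":
        return Chromosome(spec=self.spec, feature_mask=self.feature_mask.copy())

    def to_json(self) -> dict:
        return {
            "spec": self.spec.to_json(),
            "feature_mask": "".join("1" if b else "0" for b in self.feature_mask),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Chromosome":
        return cls(
            spec=ClassifierSpec.from_json(obj["spec"]),
            feature_mask=np.array([c == "1" for c in obj["feature_mask"]], dtype=bool),
        )


class ObjectiveVector(NamedTuple):
    """(precision ↑, recall ↑, n_features ↓) with Pareto-dominance semantics."""

    precision: float
    recall: float
    n_features: int

    def dominates(self, other: "ObjectiveVector") -> bool:
        ge = (
            self.precision >= other.precision
            and self.recall >= other.recall
            and self.n_features <= other.n_features
        )
        strict = (
            self.precision > other.precision
            or self.recall > other.recall
            or self.n_features < other.n_features
        )
        return ge and strict

    @classmethod
    def of(cls, res: EvalResult) -> "ObjectiveVector":
        return cls(res.precision, res.recall, res.n_features)


@dataclass
class FrontMember:
    chromosome: Chromosome
    result: EvalResult
    rank: int
    crowding: float

    @property
    def objectives(self) -> ObjectiveVector:
        return ObjectiveVector.of(self.result)


@dataclass
class ParetoFront:
    """Final ranked population, plus the per-generation rank-1 history."""

    members: list[FrontMember]
    history: list[list[ObjectiveVector]] = field(default_factory=list)

    def rank(self, r: int) -> list[FrontMember]:
        return [m for m in self.members if m.rank == r]

    def to_json(self) -> dict:
        return {
            "members": [
                {
                    "chromosome": m.chromosome.to_json(),
                    "objectives": m.result.to_json(),
                    "rank": m.rank,
                    "crowding": "inf" if np.isinf(m.crowding) else m.crowding,
                }
                for m in self.members
            ],
            "history": [
                [[o.precision, o.recall, o.n_features] for o in gen] for gen in self.history
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ParetoFront":
        members = []
        for m in obj["members"]:
            res = EvalResult(
                precision=m["objectives"]["precision"],
                recall=m["objectives"]["recall"],
                n_features=m["objectives"]["n_features"],
            )
            members.append(
                FrontMember(
                    chromosome=Chromosome.from_json(m["chromosome"]),
                    result=res,
                    rank=m["rank"],
                    crowding=float("inf") if m["crowding"] == "inf" else float(m["crowding"]),
                )
            )
        history = [
            [ObjectiveVector(p, r, int(n)) for p, r, n in gen] for gen in obj.get("history", [])
        ]
        return cls(members=members, history=history)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ParetoFront":
        with open(path) as fh:
            return cls.from_json(json.load(fh))

    def summary_rows(self) -> list[dict]:
        rows = []
        for m in sorted(self.members, key=lambda m: (m.rank, -m.result.f_measure)):
            rows.append(
                {
                    "rank": m.rank,
                    "classifier": m.chromosome.spec.name,
                    "params": list(m.chromosome.spec.params),
                    "precision": m.result.precision,
                    "recall": m.result.recall,
                    "n_features": m.result.n_features,
                    "f_measure": m.result.f_measure,
                }
            )
        return rows


# ---------------------------------------------------------------------------
# population construction and variation operators


def _repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def random_chromosome(n_features: int, rng: np.random.Generator) -> Chromosome:
    code = int(rng.integers(1, 5))
    params = tuple(grid[rng.integers(len(grid))] for grid in PARAM_GRIDS[code])
    mask = rng.integers(0, 2, size=n_features).astype(bool)
    return Chromosome(spec=ClassifierSpec(code, params), feature_mask=_repair_mask(mask, rng))


def init_population(pop_size: int, n_features: int, rng: np.random.Generator) -> list[Chromosome]:
    """Uniform random population: code, each parameter slot and each mask bit
    drawn uniformly; all-zero masks repaired by setting one random bit."""
    if pop_size < 2:
        raise ValidationError(f"pop_size must be >= 2, got {pop_size}")
    return [random_chromosome(n_features, rng) for _ in range(pop_size)]


def non_dominated_sort(objs: Sequence[ObjectiveVector]) -> np.ndarray:
    """Fast non-dominated sorting; returns 1-based ranks per individual.

    Identical objective vectors are mutually non-dominating and share a rank.
    """
    n = len(objs)
    if n == 0:
        raise ValidationError("cannot sort an empty population")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominators = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            if objs[i].dominates(objs[j]):
                dominated_by[i].append(j)
                n_dominators[j] += 1
            elif objs[j].dominates(objs[i]):
                dominated_by[j].append(i)
                n_dominators[i] += 1
    ranks = np.zeros(n, dtype=np.int64)
    current = [i for i in range(n) if n_dominators[i] == 0]
    r = 1
    while current:
        nxt: list[int] = []
        for i in current:
            ranks[i] = r
            for j in dominated_by[i]:
                n_dominators[j] -= 1
                if n_dominators[j] == 0:
                    nxt.append(j)
        current = nxt
        r += 1
    return ranks


def crowding_distance(objs: Sequence[ObjectiveVector]) -> np.ndarray:
    """Crowding distance within one rank.

    Per objective, solutions are sorted and each interior solution accrues
    the gap between its neighbors normalized by the objective's range;
    boundary solutions get +inf.  A zero-range objective contributes 0.
    """
    n = len(objs)
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    arr = np.asarray([[o.precision, o.recall, o.n_features] for o in objs], dtype=np.float64)
    for m in range(arr.shape[1]):
        order = np.argsort(arr[:, m], kind="stable")
        vals = arr[order, m]
        rng_m = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng_m > 0:
            contrib = (vals[2:] - vals[:-2]) / rng_m
            for pos in range(1, n - 1):
                if not np.isinf(dist[order[pos]]):
                    dist[order[pos]] += contrib[pos - 1]
    return dist


def crossover(
    a: Chromosome, b: Chromosome, p_cross: float, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover on the feature part only; specs copy unchanged."""
    if a.feature_mask.size != b.feature_mask.size:
        raise ValidationError("mask length mismatch between parents")
    ma, mb = a.feature_mask.copy(), b.feature_mask.copy()
    n = ma.size
    if n > 1 and rng.random() < p_cross:
        cut = int(rng.integers(1, n))
        ma[cut:], mb[cut:] = b.feature_mask[cut:].copy(), a.feature_mask[cut:].copy()
    return (
        Chromosome(spec=a.spec, feature_mask=_repair_mask(ma, rng)),
        Chromosome(spec=b.spec, feature_mask=_repair_mask(mb, rng)),
    )


def _flip_bits(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(mask.size) < (1.0 / mask.size)
    return mask ^ flips


def mutate(c: Chromosome, p_mut: float, rng: np.random.Generator) -> Chromosome:
    """Apply one of three mutation flavors with probability ``p_mut``.

    Type 1 rewrites the whole string (new code, new parameters from the new
    code's grid, per-bit mask flips at rate 1/n); type 2 rewrites parameters
    and flips mask bits; type 3 flips mask bits only.  The flavor is chosen
    uniformly per mutation event.
    """
    if rng.random() >= p_mut:
        return c.copy()
    mtype = int(rng.integers(1, 4))
    spec = c.spec
    if mtype == 1:
        code = int(rng.integers(1, 5))
        params = tuple(grid[rng.integers(len(grid))] for grid in PARAM_GRIDS[code])
        spec = ClassifierSpec(code, params)
    elif mtype == 2:
        params = tuple(grid[rng.integers(len(grid))] for grid in PARAM_GRIDS[spec.code])
        spec = ClassifierSpec(spec.code, params)
    mask = _flip_bits(c.feature_mask, rng)
    return Chromosome(spec=spec, feature_mask=_repair_mask(mask, rng))


# ---------------------------------------------------------------------------
# the generational loop


def _tournament(
    idx_pool: np.ndarray,
    ranks: np.ndarray,
    crowd: np.ndarray,
    rng: np.random.Generator,
) -> int:
    i, j = rng.integers(len(idx_pool)), rng.integers(len(idx_pool))
    a, b = idx_pool[i], idx_pool[j]
    if ranks[a] != ranks[b]:
        return int(a if ranks[a] < ranks[b] else b)
    if crowd[a] != crowd[b]:
        return int(a if crowd[a] > crowd[b] else b)
    return int(a)


def _rank_and_crowd(objs: list[ObjectiveVector]) -> tuple[np.ndarray, np.ndarray]:
    ranks = non_dominated_sort(objs)
    crowd = np.zeros(len(objs))
    for r in range(1, int(ranks.max()) + 1):
        idx = np.flatnonzero(ranks == r)
        crowd[idx] = crowding_distance([objs[i] for i in idx])
    return ranks, crowd


def run_nsga2(
    data: Dataset,
    pop_size: int = 52,
    n_generations: int = 50,
    p_cross: float = 0.9,
    p_mut: float = 0.1,
    seed: int = 0,
) -> ParetoFront:
    """Run the stage-1 search and return the final ranked population.

    Deterministic given ``seed``.  Defaults follow the published study
    conditions (population 52, 50 generations, crossover 0.9, mutation 0.1).
    """
    if pop_size % 2 != 0:
        raise ValidationError(f"pop_size must be even, got {pop_size}")
    rng = np.random.default_rng(derive_seed(seed, 1))
    eval_seed = derive_seed(seed, 2)
    cache: dict[tuple, EvalResult] = {}

    def evaluate(c: Chromosome) -> EvalResult:
        key = c.key()
        if key not in cache:
            cache[key] = loocv_evaluate(c.spec, data, c.feature_mask, eval_seed)
        return cache[key]

    pop = init_population(pop_size, data.n_features, rng)
    results = [evaluate(c) for c in pop]
    objs = [ObjectiveVector.of(r) for r in results]
    ranks, crowd = _rank_and_crowd(objs)
    history: list[list[ObjectiveVector]] = [
        [objs[i] for i in np.flatnonzero(ranks == 1)]
    ]
    _log_generation(0, objs, ranks)

    for gen in range(1, n_generations + 1):
        # mating pool via binary tournament on (rank, crowding)
        pool_idx = np.arange(pop_size)
        offspring: list[Chromosome] = []
        while len(offspring) < pop_size:
            pa = pop[_tournament(pool_idx, ranks, crowd, rng)]
            pb = pop[_tournament(pool_idx, ranks, crowd, rng)]
            ca, cb = crossover(pa, pb, p_cross, rng)
            offspring.append(mutate(ca, p_mut, rng))
            if len(offspring) < pop_size:
                offspring.append(mutate(cb, p_mut, rng))

        merged = pop + offspring
        merged_results = results + [evaluate(c) for c in offspring]
        merged_objs = [ObjectiveVector.of(r) for r in merged_results]
        m_ranks, m_crowd = _rank_and_crowd(merged_objs)

        # elitist truncation: fill by rank, break the last rank by crowding
        order = np.lexsort((np.arange(len(merged)), -m_crowd, m_ranks))
        keep = order[:pop_size]
        pop = [merged[i] for i in keep]
        results = [merged_results[i] for i in keep]
        objs = [merged_objs[i] for i in keep]
        ranks, crowd = _rank_and_crowd(objs)
        history.append([objs[i] for i in np.flatnonzero(ranks == 1)])
        _log_generation(gen, objs, ranks)

    members = [
        FrontMember(chromosome=pop[i], result=results[i], rank=int(ranks[i]), crowding=float(crowd[i]))
        for i in range(pop_size)
    ]
    return ParetoFront(members=members, history=history)


def _log_generation(gen: int, objs: list[ObjectiveVector], ranks: np.ndarray) -> None:
    front = [objs[i] for i in np.flatnonzero(ranks == 1)]
    best_p = max(o.precision for o in front)
    best_r = max(o.recall for o in front)
    min_f = min(o.n_features for o in front)
    logger.info(
        "generation %d: rank-1 size=%d best precision=%.4f best recall=%.4f min features=%d",
        gen, len(front), best_p, best_r, min_f,
    )


def unique_rank1(front: ParetoFront) -> list[tuple[Chromosome, EvalResult]]:
    """Deduplicated rank-1 solutions, ordered by descending F-measure
    (ties: fewer features, then first occurrence)."""
    if not front.members:
        raise ValidationError("empty Pareto front")
    seen: dict[tuple, tuple[Chromosome, EvalResult]] = {}
    order: list[tuple] = []
    for m in front.members:
        if m.rank != 1:
            continue
        k = m.chromosome.key()
        if k not in seen:
            seen[k] = (m.chromosome, m.result)
            order.append(k)
    if not seen:
        raise ValidationError("front has no rank-1 members")
    first_pos = {k: i for i, k in enumerate(order)}
    order.sort(key=lambda k: (-seen[k][1].f_measure, seen[k][1].n_features, first_pos[k]))
    return [seen[k] for k in order]


def hypervolume(objs: Sequence[ObjectiveVector], ref_n_features: int) -> float:
    """Hypervolume of a maximization set against reference (0, 0, ref).

    n_features is converted to the maximized quantity ref_n_features − n;
    points not strictly better than the reference contribute nothing.
    """
    pts = [
        (o.precision, o.recall, float(ref_n_features) - o.n_features)
        for o in objs
        if o.precision > 0 and o.recall > 0 and o.n_features < ref_n_features
    ]
    if not pts:
        return 0.0
    # slice along z: between consecutive z-levels the volume is the 2-D
    # dominated area of all points at or above that level
    zs = sorted({p[2] for p in pts}, reverse=True)
    zs.append(0.0)
    vol = 0.0
    for level, nxt in zip(zs[:-1], zs[1:]):
        xy = [(p[0], p[1]) for p in pts if p[2] >= level]
        vol += (level - nxt) * _area2d(xy)
    return vol


def _area2d(points: list[tuple[float, float]]) -> float:
    pts = sorted(points, key=lambda p: (-p[0], -p[1]))
    area = 0.0
    prev_x = None
    best_y = 0.0
    # sweep x descending, accumulating rectangles above the running max y
    for x, y in pts:
        if y > best_y:
            area += x * (y - best_y)
            best_y = y
        prev_x = x
    return area
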