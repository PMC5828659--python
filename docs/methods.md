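# Methods

## Problem setting and model

Given a labeled samples × features expression matrix (typically tens of
samples, hundreds to thousands of features), the package selects — in one
search — a classifier family, its hyperparameters, and a feature subset,
then fuses the set of non-dominated solutions into a single predictor.

Stage 1 treats the selection as a three-objective optimization problem.
A candidate solution is a chromosome with three parts: a classifier code
(1 = RF, 2 = RT, 3 = SMO, 4 = LR), the hyperparameter slot values drawn
from that code's grid, and a binary feature-inclusion mask. A candidate's
fitness is measured by leave-one-out cross-validation (LOOCV) on the
training split: the model is refit n times, each time predicting the one
held-out sample, and the pooled (truth, prediction) pairs give

* macro-averaged precision — maximized,
* macro-averaged recall — maximized,
* the popcount of the feature mask — minimized.

Solution quality is compared by Pareto dominance: a solution dominates
another if it is at least as good on all three objectives and strictly
better on one. Equal objective vectors are mutually non-dominating.

Stage 2 converts the rank-1 front into one predictor by stacking. The
unique rank-1 solutions (deduplicated on the full chromosome) are refit on
the training split, each restricted to its own mask, and their predicted
class codes are appended to the feature matrix as columns P_1..P_N — for
both training and test sets, always using the train-fitted models. The
base solution with the highest LOOCV F-measure (harmonic mean of the
stage-1 precision and recall) is retrained on the augmented training
matrix as the meta-learner, and its accuracy on the augmented test set is
the reported final accuracy.

## Assumptions

* Features are numeric and comparable across samples after optional
  per-sample normalization; labels are categorical with ≥ 2 classes.
* LOOCV is an acceptable objective estimator, which presumes small n (it
  costs n fits per candidate) and tolerates its known high variance.
* Macro averaging treats classes symmetrically, appropriate for imbalanced
  biomarker panels; a class never predicted contributes precision 0 rather
  than NaN so the objectives stay total.
* The in-sample augmentation of the training set (base predictions on the
  very data they were fit on) follows the stacking recipe as specified; it
  is optimistic for flexible bases. Out-of-fold stacking is deliberately
  not implemented — the test-set accuracy remains honest because test
  augmentation only ever uses train-fitted models.

## Base learners and Weka-convention mappings

The four learners stand on scikit-learn; two grid semantics needed an
explicit mapping from their decision-tree heritage:

* *split features = 0* → the `int(log2(m)) + 1` heuristic on the m masked
  features (floored at 1); nonzero values are clipped to m.
* *RT minimum total leaf weight* ∈ {1.0, 1.05, 1.25} → `min_samples_leaf =
  ceil(weight)` ∈ {1, 2, 2}: the closest integral semantic outside a
  fractional-instance-weight implementation.
* *SMO complexity* → the box constraint C of a linear-kernel SVC; only C is
  in the grid, so no other kernel is searched.
* LR runs at library defaults with `max_iter = 1000` for convergence on
  standardized expression values.

Bit-exact reproduction of Weka's internals is a non-goal; the grids,
encodings and protocol are what the package preserves.

## Genetic algorithm details

* **Initialization**: code uniform on {1..4}, each parameter slot uniform
  on its grid, each mask bit uniform on {0, 1}; an all-zero mask is
  repaired by setting one uniformly chosen bit (LOOCV needs ≥ 1 feature).
  Repair-not-penalize applies everywhere a mask could become empty.
* **Selection**: binary tournament on (rank, crowding distance).
* **Crossover** (probability 0.9 per pair): single-point on the feature
  part only, cut uniform in [1, n−1]; classifier and parameter parts copy
  unchanged from each parent.
* **Mutation** (probability 0.1 per offspring): one of three flavors,
  chosen uniformly per event — type 1 resamples the classifier code, then
  all parameter slots from the *new* code's grid, then flips each mask bit
  with rate 1/n; type 2 resamples parameters and flips mask bits; type 3
  flips mask bits only. Uniform flavor choice and the 1/n per-bit flip
  rate are maximum-entropy defaults where no rates were prescribed.
* **Survival**: parents and offspring are merged and truncated to the
  population size by (rank, crowding), i.e. the standard elitist scheme;
  within the last admitted rank, higher crowding survives, remaining ties
  broken by position for determinism.
* **Crowding distance**: per objective, interior solutions accrue the
  neighbor gap normalized by that objective's range over the front;
  extremes get +∞; a zero-range objective contributes 0.
* **Defaults**: population 52, 50 generations, crossover 0.9, mutation 0.1
  — the published study conditions. The generation count is configurable
  (the source protocol mentions both 50 and 100; 50 is the default here).
* **Caching**: objective evaluation is memoized on (code, params, mask).
  LOOCV dominates runtime and duplicate chromosomes are common once the
  population converges, so the cache typically saves 30–60 % of fits.
* **Seeding**: one run seed fans out through a fixed SeedSequence
  derivation to the GA stream, a per-run evaluation seed, and per-fold
  model seeds (derived from fold index), keeping runs exactly reproducible
  while avoiding identically seeded folds. All derived seeds are < 2³¹.

## Stacking details

* The meta-learner sees the original features plus all N prediction
  columns (`meta_features="all"`). Alternatives `"mask+preds"` (the best
  base's panel plus predictions) and `"preds-only"` are provided; whole-
  matrix augmentation is the default because the stacking recipe appends
  predictions to the existing feature set rather than replacing it.
* Binary problems use a single meta-model on the 0/1 class codes (the
  positive-class-is-1 convention is exposed as `binarize_labels`). With
  k > 2 classes, one meta-model per class is trained one-vs-rest and the
  predicted label is the class with the highest positive score — decision
  function where available, positive-class probability otherwise, hard
  labels as a last resort — with ties resolved to the lowest class code.
  With two classes this reduces to the single binary model, which a test
  verifies.

## Preprocessing conventions

* χ² ranking: continuous features are discretized into equal-frequency
  bins (default 10; features with ≤ n_bins distinct values pass through as
  categories), then scored by the χ² test of independence against the
  class, without continuity correction. Constant features score 0. Top-k
  selection breaks ties by ascending feature index.
* SNR filter: two classes only; σ is the sample standard deviation
  (ddof = 1); a feature with σ₁+σ₂ = 0 gets SNR 0 with a warning. Both
  sides of the threshold use absolute values, so selection is invariant to
  which class is called positive.
* Per-sample normalization scales each row to mean 0 and unit population
  variance (ddof = 0); the transform is idempotent and a constant row is
  an error naming the sample.
* In the pipeline, scorers are fit on the training split only and applied
  to both splits — the leak-free default. A `fit_on="all"` escape hatch
  reproduces protocols that filtered before splitting.

## Stratified splitting

Per class, the training set receives round-half-up(fraction × count)
samples, clamped so both splits keep at least one sample of every class;
the remainder goes to test. Assignment within a class is seeded-random;
outputs preserve original row order, and row identity (source-file row
index) is tracked so tests can verify the split is a partition. Classes
with a single sample are rejected.

## Synthetic data generator

`generate(SynthConfig)` emulates the structure the method assumes: class c
adds a mean shift of c × effect_size to the first `n_informative` features;
everything else is N(0, noise_sd²) noise; feature names flag planted
markers. Defaults (25 samples/class, 100 features, 5 informative, effect
size 3, unit noise) represent a small two-class miRNA-style study with
clearly but not trivially separable classes. `perfectly_separable()` plants
one noiseless feature equal to the class code, giving a known search
optimum of (1, 1, 1).

What the generator does *not* emulate: count-distribution noise (negative
binomial), feature–feature correlation, batch effects, and class
imbalance. Passing tests therefore demonstrate that the machinery is
correct and that the method recovers planted Gaussian-shift structure —
not that it attains any particular accuracy on real expression data.

## Problem sizes in tests and the acceptance script

LOOCV makes each objective evaluation cost n model fits, so the bundled
runs use deliberately small instances: the planted-optimum search runs
population 20 for 15 generations on 50 samples × 20 features; the
stacking-vs-best-base comparison runs 10 end-to-end seeds at population 10,
5 generations, 24 samples; `scripts/acceptance.py` runs population 16 for
10 generations on 50 samples × 100 features after SNR filtering. These
sizes are the package's own defaults for its self-checks; the published
study conditions (population 52, 50 generations) remain the API defaults.

## Known limitations

* NSGA-II hypervolume is monitored per generation but not used for
  termination; very large rank-1 fronts can in principle lose interior
  solutions at truncation.
* The RT mapping cannot express fractional leaf weights exactly; 1.05 and
  1.25 collapse to the same constraint.
* LOOCV objectives are high-variance at small n; identical objective
  vectors from different chromosomes are common, which the dedup step and
  the caching layer both exploit but the search cannot distinguish.
* Multiclass support enters only at the stacking stage (one-vs-rest); the
  SNR filter remains strictly two-class.
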