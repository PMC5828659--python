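# stackselect

Automatic classifier selection for expression biomarker data, in two stages:

1. **Multiobjective search.** An elitist NSGA-II explores a three-part
   chromosome — classifier type, its hyperparameters, and a binary feature
   mask — scoring every candidate by leave-one-out cross-validation on three
   objectives: macro precision (maximize), macro recall (maximize) and the
   number of selected features (minimize). The result is a Pareto front of
   non-dominated (classifier, parameters, marker panel) solutions.
2. **Stacked ensemble.** The unique rank-1 solutions become base learners:
   each is refit on the training split and its predicted class codes are
   appended to the feature matrix as new columns P_1..P_N. The base with the
   highest F-measure is retrained on the augmented matrix as the
   meta-learner; its test accuracy is the final accuracy of the combined
   solution. Problems with more than two classes are decomposed one-vs-rest
   at the meta level.

The intended users are computational biologists classifying tumor vs.
normal samples from miRNA/mRNA expression matrices (few samples, thousands
of features), where no single classifier family wins across datasets and
a small interpretable marker panel matters as much as accuracy.

## What is searched

Candidate learners and their hyperparameter grids:

| code | learner | grid |
|------|---------|------|
| 1 | random forest (RF) | trees ∈ {10, 20, 30}; split features ∈ {0, 5, 6} |
| 2 | random tree (RT) | min leaf weight ∈ {1.0, 1.05, 1.25}; split features ∈ {0, 3, 7} |
| 3 | SMO (linear SVM) | complexity C ∈ {1, 3, 8} |
| 4 | logistic regression (LR) | defaults |

A split-feature value of 0 means the classic `int(log2(m)) + 1` heuristic.
Two filter preprocessors can shrink the feature space first: χ² attribute
ranking (top-k after equal-frequency discretization) and per-sample
normalization followed by signal-to-noise-ratio filtering,
SNR = (μ₁−μ₂)/(σ₁+σ₂), keeping features with |SNR| ≥ mean |SNR|.

## Worked example

A dataset whose first feature equals the class label exactly has a known
optimum: any classifier on just that feature scores (precision 1, recall 1,
1 feature). A short seeded search recovers it
(`python examples/03_stage1_search.py`):

```
rank-1 solutions (classifier, params, precision, recall, #features):
   RF      (30, 6)  P=1.000 R=1.000 k=1
  SMO         (8,)  P=1.000 R=1.000 k=1
  SMO         (3,)  P=1.000 R=1.000 k=1
best solution reaches (1.0, 1.0, 1) -> the planted single-marker optimum
```

Each line is one unique rank-1 solution: the learner it chose, its
hyperparameters, the LOOCV macro precision/recall and the marker-panel
size. Three distinct classifier configurations all found the single planted
marker — exactly the kind of redundancy stage 2 then fuses.

The other scripts in `examples/` walk through data generation, the two
preprocessing paths, the stacked ensemble, and the end-to-end pipeline.
The same pipeline is available from the shell:

```sh
stackselect synth --n-per-class 25 --n-features 100 --n-informative 5 \
    --effect 3 --seed 1 --out data.csv
stackselect run --data data.csv --preprocess snr --pop-size 52 \
    --generations 50 --seed 1 --out-dir out/
```

which writes `front.json` (the ranked population), `report.json` (per-base
and stacked accuracies plus selected marker names) and `run.log`
(per-generation objective traces). Identical config and seed reproduce
both JSON files byte for byte.

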