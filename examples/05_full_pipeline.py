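"""The whole tool in one call: split -> preprocess -> search -> stack -> report.

Equivalent to the CLI `stackselect run`; writes front.json (the ranked
Pareto population), report.json (per-base and stacked accuracies plus the
selected marker names) and run.log (per-generation objective traces).
"""

import json
from pathlib import Path

from stackselect import RunConfig, run_pipeline

out_dir = Path("scratch_example_out")
report = run_pipeline(
    RunConfig(
        data=None,  # no file -> generate synthetic data
        synth={"n_per_class": 15, "n_features": 40, "n_informative": 3,
               "effect_size": 4.0, "seed": 2},
        preprocess="snr",
        pop_size=12,
        n_generations=6,
        seed=4,
        out_dir=str(out_dir),
    )
)

print(f"unique rank-1 solutions: {report['n_unique_solutions']}")
print(f"meta-learner: {report['meta_classifier']} {report['meta_params']}")
print(f"final stacked test accuracy: {report['final_accuracy']:.3f}")
print(f"marker panel of the best base: {report['bases'][0]['selected_features']}")
print(f"outputs written to {out_dir}/: "
      + ", ".join(p.name for p in sorted(out_dir.iterdir())))
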