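"""Generate a synthetic two-class expression matrix with planted markers.

Five informative features are mean-shifted between the classes by 3 noise
standard deviations; the other 95 features are pure noise.  The printed SNR
values show why the planted features are recoverable: their class
separation dwarfs anything noise produces by chance.
"""

import numpy as np

import stackselect as ss

data = ss.generate(
    ss.SynthConfig(n_per_class=25, n_features=100, n_informative=5,
                   effect_size=3.0, seed=1)
)
print(f"dataset: {data.n_samples} samples x {data.n_features} features, "
      f"classes {data.class_names}")

table = ss.snr_filter(data)
scores = np.abs(table.scores)
print(f"planted features |SNR|: {np.round(scores[:5], 2)}")
print(f"strongest noise feature |SNR|: {scores[5:].max():.2f}")
print("-> each planted marker separates the classes far better than any noise feature")
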