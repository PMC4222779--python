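"""Generating a synthetic ontogenetic landmark study.

Simulates the default design — 10/9/10 specimens at E10.5/E11.5/E12.5,
4 observers (3 experienced + 1 novice), 2 placement trials — and shows the
generative components recorded in the ground truth.
"""

import numpy as np

from embryomorph import SimParams, centroid_size, default_design, simulate_dataset

params = default_design()
print("design (specimens per age, observers, trials):", params.design)
print(f"growth targets (centroid size, mm): {dict(params.growth)}")
print(f"trial noise s.d. per observer (mm): {params.sigma_trial}"
      " (the last observer is the novice)")

dataset, truth = simulate_dataset(params, seed=1)
print(f"\nsimulated {len(dataset.configurations)} configurations "
      f"({29} specimens x 4 observers x 2 trials)")

cs = [
    centroid_size(truth.true_shapes[key]) for key in sorted(truth.true_shapes)
]
print(f"specimen centroid sizes span {min(cs):.2f}-{max(cs):.2f} mm, "
      "growing with age")
print(f"allometric slope (shape displacement per mm of size): "
      f"{truth.allometry_slope:.3f}")
print("the slope default is calibrated so the size-correlated signal "
      "accounts for ~80% of shape variance")

# determinism: the same parameters and seed reproduce the data bit for bit
d2, _ = simulate_dataset(params, seed=1)
identical = all(
    np.array_equal(a.array(dataset.scheme), b.array(dataset.scheme))
    for a, b in zip(dataset.configurations, d2.configurations)
)
print(f"re-simulation with the same seed identical: {identical}")
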