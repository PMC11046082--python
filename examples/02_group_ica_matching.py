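"""Group ICA per condition and cross-condition component matching.

Simulates stop-trial EEG for a small cohort from four known source
topographies, decomposes each condition separately (PCA retention +
fixed-point ICA, C = WX), and matches components across conditions by
the correlation of their topographies.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

import conflictstop as cs

truth = cs.default_ground_truth(n_subjects=8, seed=3)
epochs = cs.simulate_epochs(truth, n_trials_per_condition=40)

decomp_c = cs.decompose_condition(epochs, "congruent", seed=1)
decomp_i = cs.decompose_condition(epochs, "incongruent", seed=2)
print(f"retained {decomp_c.n_retained} components per condition "
      f"(98% eigenvalue retention, cap 20)")

topos = np.stack([s.topography for s in truth.sources])
for name, d in (("congruent", decomp_c), ("incongruent", decomp_i)):
    R = np.abs(topos @ d.A)
    ri, ci = linear_sum_assignment(-R)
    print(f"{name:>12}: |r| with ground-truth topographies = {R[ri, ci].round(3)}")

pairs = cs.match_components(decomp_c, decomp_i, threshold=0.85, seed=5)
print(f"\n{len(pairs)} matched pairs at |r| >= 0.85:")
for k, p in enumerate(pairs, 1):
    print(f"  pair {k}: IC{p.index_congruent} <-> IC{p.index_incongruent}, "
          f"r = {p.correlation:+.3f}{'  (sign-flipped)' if p.sign_flip else ''}")
print("-> only the genuine sources survive the 0.85 threshold; the"
      " condition-specific background components do not match.")
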