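"""Time-resolved decoding of the congruency effect with cluster inference.

Decodes congruent vs. incongruent stop trials per subject on the
ground-truth component of the earliest source (window 85-245 ms), then
tests the group AUC time course against chance with a sign-flip cluster
permutation test.
"""

import numpy as np

import conflictstop as cs
from conflictstop.inference import cluster_permutation

truth = cs.default_ground_truth(n_subjects=8, seed=11)
epochs = cs.simulate_epochs(truth, n_trials_per_condition=60)
times = epochs.times
topo = truth.sources[0].topography
lo, hi = truth.sources[0].window_ms

aucs = []
for sub in epochs.subjects:
    comp = {
        cond: topo[None, :, None]
        * np.einsum("c,tcs->ts", topo, epochs.get(sub, cond))[:, None, :]
        for cond in ("congruent", "incongruent")
    }
    res = cs.decode_timecourse(comp["congruent"], comp["incongruent"], seed=5)
    aucs.append(res.auc_diag)
aucs = np.stack(aucs)

result = cluster_permutation(aucs, alpha_cluster=0.05, n_perm=1000, seed=9)
print(f"true effect window: {lo:.0f}-{hi:.0f} ms "
      f"(effect size d = {truth.sources[0].effect_size})")
for c in result.significant(0.05):
    a, b = c.extent_1d()
    print(f"significant cluster: {times[a]:.0f}-{times[b]:.0f} ms, "
          f"mass {c.mass:.1f}, p = {c.p:.4f}")
peak = aucs.mean(0).argmax()
print(f"peak group AUC {aucs.mean(0)[peak]:.3f} at {times[peak]:.0f} ms")
print("-> the cluster test localizes the decodable window without"
      " inflating the family-wise error over 307 samples.")
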