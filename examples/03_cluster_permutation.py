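"""Cluster-based permutation test on a participant x time effect.

Simulates 20 participants' condition-difference timecourses with a real
effect confined to samples 20-30, runs the temporal cluster test, and shows
that the recovered significant cluster covers the injected window while a
pure-noise dataset yields none.
"""
import numpy as np

from noreport import clusterstat as cs

rng = np.random.default_rng(0)
n_participants, n_samples = 20, 50

signal = rng.normal(0, 1, (n_participants, n_samples))
signal[:, 20:30] += 0.8  # injected effect

res = cs.permutation_test(
    cs.DataCube(signal), cs.ClusterTestConfig(n_perm=1000, seed=1)
)
print(f"cluster-forming |t| threshold: {res.threshold_t:.2f} "
      f"(two-tailed p < 0.05, df = {n_participants - 1})")
for c in res.significant_clusters():
    samples = np.unique(c.indices % n_samples)
    print(f"significant cluster: samples {samples.min()}-{samples.max()}, "
          f"mass {c.mass:.1f}, p = {c.p_value:.4f}")

null = cs.permutation_test(
    cs.DataCube(rng.normal(0, 1, (n_participants, n_samples))),
    cs.ClusterTestConfig(n_perm=1000, seed=2),
)
print(f"pure noise: {len(null.significant_clusters())} significant clusters "
      "(family-wise error is controlled at alpha = 0.05)")
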