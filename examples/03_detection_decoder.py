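"""The population decoder: parametric binomial formula and bootstrap.

A downstream decoder watches the summed spike count of N transmitting
neurons in a window of length T after a PSC onset and declares the signal
when the count crosses the 95% (excitatory) / 5% (inhibitory) quantile of
the pre-onset count distribution.  This script evaluates the parametric
formula on a probability grid and cross-checks it with the bootstrap on
synthetic sweeps.
"""

import numpy as np

import pscmix as pm
from pscmix.detection import SweepGroup

# parametric detection over population sizes (P_pre = 0.5% baseline spiking
# per sweep; the signal raises the post-onset probability to 1.5%)
print("parametric detection, P_pre = 0.005 -> P_post = 0.015 (excitatory):")
for n in (250, 500, 1000, 2000):
    det = pm.parametric_detection(0.005, 0.015, n)
    print(f"  N = {n:4d}: detection within T = {det:.3f}")

# the null is calibrated: equal probabilities never exceed alpha
worst = max(
    pm.parametric_detection(p, p, n, 0.05, s)
    for p in (0.001, 0.02) for n in (250, 2000) for s in ("excitatory", "inhibitory")
)
print(f"\nnull ceiling (P_post = P_pre): max detection = {worst:.4f} <= alpha = 0.05")

# bootstrap cross-check on synthetic Bernoulli sweeps
rng = np.random.default_rng(0)
n_sweeps = 100_000
pre = np.nonzero(rng.random(n_sweeps) < 0.005)[0]
post = np.nonzero(rng.random(n_sweeps) < 0.015)[0]
group = SweepGroup(
    "excitatory", 0, 50.0, n_sweeps,
    np.concatenate([pre, post]),
    np.concatenate([np.full(pre.size, -2.5), np.full(post.size, 2.5)]),
    t_max=15.0,
)
wp = pm.window_probs(group, 5.0)
want = pm.parametric_detection(wp.p_pre, wp.p_post, 1000)
got, sd = pm.bootstrap_detection(group, 5.0, 1000, n_sets=100, n_reps=50, seed=1)
print(f"\nbootstrap vs parametric at N = 1000 on {n_sweeps} synthetic sweeps:")
print(f"  parametric {want:.3f}   bootstrap {got:.3f} +/- {sd:.3f} (SD over repetitions)")
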