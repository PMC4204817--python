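"""End-to-end mixture experiment at reduced scale.

Synthesizes mixture currents from 1024 model presynaptic inputs, drives the
model neuron for 4 episodes of 46 s at ~5 Hz, aligns postsynaptic spikes to
every PSC onset, and prints detection probabilities by amplitude for
excitatory and inhibitory inputs.  (The full protocol simply uses more
episodes; see the reproduce CLI subcommand.)
"""

import numpy as np

import pscmix as pm

pop = pm.build_population(
    1024, 0.5, pm.RenewalSpec(duration=46.0), pm.AmplitudeDistribution(), seed=42
)
kernel = pm.make_kernel(0.5, 5.0, 0.05)
episodes = pm.run_episodes(
    pm.NeuronParams(), pop, kernel, n_episodes=4, target_sd=100.0, target_rate=5.0
)
rates = episodes.rate_in_bins(5.0)
print(f"DC {episodes.meta['dc']:.1f} pA; mean firing rate {rates.mean():.2f} Hz "
      f"over {len(episodes.episodes)} episodes of 46 s")

sweeps = pm.collect_sweeps(episodes, t_max=15.0)
print(f"{sum(g.n_sweeps for g in sweeps.groups.values())} sweeps "
      f"across {len(sweeps.groups)} (sign, amplitude-class) groups\n")

print("detection within T = 5 ms from N = 1000 sweeps (parametric decoder):")
print("  amplitude (SD units)   excitatory   inhibitory")
bins = [(0.1, 0.25), (0.25, 0.5), (0.5, 1.0), (1.0, 3.0)]
for lo, hi in bins:
    row = []
    for sign in ("excitatory", "inhibitory"):
        classes = [
            k[1] for k in sweeps.keys()
            if k[0] == sign and lo <= sweeps.groups[k].amplitude_pA / 100.0 < hi
        ]
        if not classes:
            row.append("   n/a")
            continue
        wp = pm.window_probs(sweeps.pooled(sign, classes), 5.0)
        row.append(f"{pm.parametric_detection(wp.p_pre, wp.p_post, 1000, 0.05, sign):6.3f}")
    print(f"  {lo:4.2f} - {hi:4.2f}          {row[0]}       {row[1]}")
print("\nLarger-amplitude PSCs are detected more reliably, and excitatory")
print("inputs faster than inhibitory ones at short windows - the signature")
print("the fully-defined mixture paradigm is built to quantify.")
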