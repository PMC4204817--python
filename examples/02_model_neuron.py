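"""The model postsynaptic neuron: calibration and membrane statistics.

Shows the leaky integrate-and-fire stand-in for the recorded cell: its f-I
curve under constant current, the in-vivo-like fluctuation regime under a
mixture current (15-20 mV membrane excursions), and automatic DC
calibration to target firing rates of 1, 5 and 10 Hz.
"""

import numpy as np

import pscmix as pm

params = pm.NeuronParams()
print(f"LIF stand-in: tau_m {params.tau_m} ms, R_in {params.r_in} MOhm, "
      f"rest {params.v_rest} mV, threshold {params.v_threshold} mV")

# f-I curve under constant current
print("\nconstant-current firing rates:")
for i_pa in (150, 200, 300, 450):
    trace = pm.CurrentTrace(np.full(200_000, float(i_pa)), 0.05)
    _, spikes = pm.simulate(params, trace, paste_spikes=False)
    print(f"  I = {i_pa:4d} pA -> {pm.firing_rate(spikes, trace.duration):5.1f} Hz")

# fluctuation regime under a mixture current of SD 100 pA
pop = pm.build_population(
    1024, 0.5, pm.RenewalSpec(duration=20.0), pm.AmplitudeDistribution(), seed=3
)
kernel = pm.make_kernel(0.5, 5.0, 0.05)
current, _, _ = pm.synthesize_mixture(pop, kernel, target_sd=100.0, dc=0.0, duration=20.0)
v, _ = pm.simulate(pm.NeuronParams(v_threshold=1e9), current)  # subthreshold
spread = np.percentile(v[40_000:], 95) - np.percentile(v[40_000:], 5)
print(f"\nmembrane fluctuations under SD-100 pA mixture current: "
      f"{spread:.1f} mV (5th-95th percentile; target regime 15-20 mV)")

# DC calibration to the protocol's firing-rate targets
print("\nDC calibration (bisection on a probe episode):")
for target in (1.0, 5.0, 10.0):
    dc = pm.calibrate_dc(params, current, target)
    probe = pm.CurrentTrace(current.samples + dc, current.dt)
    _, spikes = pm.simulate(params, probe, paste_spikes=False)
    rate = pm.firing_rate(spikes, probe.duration, discard=2.0)
    print(f"  target {target:4.1f} Hz -> DC {dc:6.1f} pA, measured {rate:.2f} Hz")
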