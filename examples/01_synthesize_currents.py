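"""Synthesize injectable currents under both stimulus paradigms.

Builds (a) a signal-immersed-in-noise current — one 50 pA artificial EPSC
train in Ornstein–Uhlenbeck noise of SD 110 pA — and (b) a fully-defined
mixture current summing the PSC trains of 1024 model presynaptic neurons,
rescaled to SD 100 pA, then prints the waveform statistics.
"""

import numpy as np

import pscmix as pm

# --- paradigm 1: signal immersed in noise -------------------------------
kernel1 = pm.make_kernel(tau_rise=1.0, tau_decay=10.0, dt=0.05)
onsets = pm.sample_renewal_train(pm.RenewalSpec(duration=10.0), seed=1)
trace1, trig1 = pm.synthesize_signal_in_noise(
    pm.OUSpec(sigma=110.0), kernel1, signal_amplitude=50.0,
    signal_onsets=onsets, dc=0.0, duration=10.0, seed=1,
)
print("signal-in-noise current:")
print(f"  kernel peak time     {kernel1.peak_time:.3f} ms (rise 1, decay 10 ms)")
print(f"  {len(trig1)} aEPSC onsets in 10 s (~{len(trig1)/10:.1f} Hz)")
print(f"  trace SD             {trace1.samples.std():.1f} pA (noise 110 pA + signal)")

# --- paradigm 2: fully-defined signal mixture ---------------------------
kernel2 = pm.make_kernel(tau_rise=0.5, tau_decay=5.0, dt=0.05)
pop = pm.build_population(
    1024, 0.5, pm.RenewalSpec(duration=10.0), pm.AmplitudeDistribution(), seed=2
)
trace2, trig2, scale = pm.synthesize_mixture(pop, kernel2, target_sd=100.0, dc=0.0, duration=10.0)
amps = trig2.amplitude_pA
print("\nfully-defined mixture current (1024 inputs, 512 E / 512 I):")
print(f"  scale factor         {scale:.3f} (raw sum -> SD 100 pA)")
print(f"  trace SD             {trace2.samples.std():.1f} pA, mean {trace2.samples.mean():+.1f} pA")
print(f"  {len(trig2)} PSC onsets recorded in the trigger table")
print(f"  PSC peak amplitudes  {amps.min():.2f} - {amps.max():.1f} pA "
      f"({amps.min()/100:.4f} - {amps.max()/100:.2f} in units of the current SD)")
print("\nEvery onset in the trigger table is a known 'signal'; the sum of all")
print("other PSCs is that signal's 'noise' - the basis of the mixture paradigm.")
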