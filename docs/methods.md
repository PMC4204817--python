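# Methods notes

This note records the models implemented, the parameter choices that
matter, the numerical conventions, and what the built-in model neuron does
and does not establish.

## Presynaptic population

Each model presynaptic neuron fires as an **ordinary gamma renewal
process**: i.i.d. inter-spike intervals from Gamma(shape k, scale θ) with
the scale derived from the target mean rate, θ = (1000/rate)/k ms (k = 2,
rate = 5 Hz → θ = 100 ms by default). Intervals below a 10 ms floor are
**redrawn until valid** (rejection, not truncation-shift), which keeps the
renewal structure while preventing strongly overlapping PSCs from one
input. The first interval is drawn from the same gamma (ordinary, not
equilibrium, renewal); over 46 s episodes with the first 2 s discarded the
transient is irrelevant.

Two consequences of the redraw rule worth knowing:

* the realized mean rate is ≈ 0.5% below the nominal rate (the floor
  removes ~0.5% of interval mass at the defaults);
* a plain two-parameter ML gamma fit to the output intervals is biased
  to shape ≈ 2.08 (+4%), because deleting the left tail raises the
  log-mean that the shape estimate is sensitive to.
  `fit_gamma_shape(isis, floor_ms=10)` maximizes the correct conditional
  likelihood (gamma given ISI ≥ floor) and recovers k = 2 within sampling
  error; both fits are exposed.

**Amplitudes** are drawn from a 32-level discretization of a log-normal
(μ = 0.702, σ = 0.9355 in log-pA): levels log-spaced over μ ± 3.5σ, each
carrying the exact log-normal mass of its bin with the tails folded into
the edge bins. The ±3.5σ span keeps the recovered log-moments within ~0.3%
of (μ, σ); the span is configurable. Excitatory and inhibitory neurons use
the same distribution — the sign is a separate label — so the summed input
is balanced *in law*. Amplitude assignment is i.i.d. per neuron by default;
`stratified=True` pins the realized histogram to the distribution by
largest-remainder quota. Note that with i.i.d. assignment a single fixed
roster has a nonzero net drive (the E and I amplitude sums differ by
sampling), which appears as a persistent pre-DC mean of order ±30 pA; it is
absorbed by the DC calibration and averages to zero over rosters.

**RNG scheme:** every spike train is keyed by
`SeedSequence([master_seed, episode, neuron_id])`, so populations are
bit-reproducible and any single neuron/episode can be regenerated in
isolation. Episode `e` of a protocol uses key `e + 1`; key 0 is the roster
build.

## Current synthesis

PSC kernels are differences of two exponentials normalized to **unit peak
on the sample grid**, so "amplitude" equals the rendered PSC peak in pA
exactly. "Rise/decay time" means the two exponential time constants (the
standard convention for this kernel), not 10–90% times. Kernels are
truncated where the waveform falls below 10⁻⁴ of peak (≈ 9 decay
constants); onsets snap to the nearest sample of the 20 kHz grid
(dt = 0.05 ms default). Rendering places signed delta impulses for the
whole population on the grid and convolves once with the shared kernel
(FFT), which is identical to per-neuron rendering by linearity (tested).

OU noise uses the exact discretization
`x[n+1] = x[n]·e^(−dt/τ) + σ·√(1−e^(−2dt/τ))·ξ[n]` with a stationary start,
so variance and autocorrelation are exact at any step size.

**Scaling.** In the mixture paradigm the zero-DC population sum is globally
rescaled so its sample SD equals `target_sd` (default 100 pA, in the
70–110 pA range that yields the in-vivo-like fluctuation regime); DC is
added afterwards. The scale factor is reported, and trigger-table
amplitudes are post-scaling, so amplitudes are directly expressible in
units of the injected-current SD — the natural axis for detection surfaces.
Per-episode rescaling (each episode hits the target SD exactly) was chosen
over a fixed global factor; the episode-to-episode scale jitter is < 1%.

## Model neuron

A leaky integrate-and-fire neuron (exponential Euler at the trace dt;
optional exponential spike-initiation term, off by default): τ_m = 20 ms,
R_in = 130 MΩ, rest −70 mV, threshold −50 mV, reset −60 mV, refractory
2 ms. R_in was set so that a mixture current of SD 100 pA produces
membrane fluctuations with a 5th–95th percentile range inside 15–20 mV
(measured ≈ 18 mV), the regime the stimulus is designed for; the other
values are textbook cortical-pyramidal numbers. The model is a **calibrated
stand-in** for a real recorded cell: detection *magnitudes* it produces are
not predictions for any real neuron, but the directional structure
(amplitude, window, population-size, rate and E/I dependences) is what the
tests assert.

Threshold crossings are registered without sub-dt interpolation (error
≤ 0.05 ms, below every analysis bin). Because an integrate-and-fire model
has no overshoot, a stylized 2 ms triangular spike to +30 mV is pasted into
returned voltage traces so the **positive-zero-crossing** spike-detection
rule used for real recordings runs end to end; `detect_spikes` agrees with
the simulator's registry to within the 1 ms rise of that stylized shape.

**DC calibration** bisects the offset on a probe episode until the
post-discard rate is within 5% of target (bracket −200…600 pA, 10
bisection steps). The protocol runs 46 s episodes, discards the first 2 s,
and logs rate in 5 s bins; each episode re-realizes all presynaptic trains
from its own substream while the roster and DC stay fixed.

## Detection analysis

Sweeps are spikes within ±T_max (15 ms) of each PSC onset, grouped by
(sign, amplitude class); onsets inside the discard window or within T_max
of an episode edge are dropped, and consecutive onsets closer than 2·T_max
are both kept (same-neuron overlap is limited by the 10 ms ISI floor).
Windows are [−T, 0) and [0, T). Both the spike-indicator and spike-count
estimators of P_pre/P_post are computed; at the short windows and rates
used they coincide (asserted in tests).

The **parametric decoder** uses the binomial quantile convention
"smallest k with CDF ≥ p" and strict comparisons, which guarantees the
null (P_post = P_pre) never exceeds α. The **bootstrap decoder** draws
`n_sets` trial sets of N sweeps with replacement (per repetition), takes
the empirical quantile of the set-level *pre-window count sums pooled over
all trial sets* as the threshold, counts the sets whose post-window sum
crosses it strictly, and reports mean ± SD over `n_reps` repetitions
(defaults 100/100). The empirical quantile uses the same
smallest-value-with-ECDF ≥ p convention. The bootstrap is intended for
sweep pools much larger than N (the experimental situation); with pools of
order N the threshold and the tested sums share sampling noise and the two
estimators drift apart by a few hundredths.

PSTHs normalize counts to rate: `count / (n_sweeps · bin)`, bin 0.5 ms by
default (configurable). The T grid defaults to 0.4–15 ms in 0.4 ms steps.
No multiple-testing correction is applied across amplitude classes sharing
one recording — each class is treated independently, which users combining
classes into claims should keep in mind.

## What the synthetic data does and does not establish

The generator reproduces the *statistical structure* of the stimulus
(renewal trains, log-normal amplitudes, balanced E/I, OU-like background)
and the model neuron supplies a plausible spike encoder. Passing tests
establish that the decoders are correctly calibrated (null ≤ α), that
parametric and bootstrap estimates agree in the regime the method is used
in, and that detection grows with amplitude, window length, population
size and firing rate with excitation detected faster than inhibition at
short windows. They do **not** establish quantitative detection values for
real neurons: real cells have adaptation, conductance state, dendritic
filtering and spike-initiation dynamics the stand-in lacks. Correlated
presynaptic firing, heterogeneous rates and short-term plasticity are
deliberately out of scope (extension points).

## Test problem sizes

The test suite simulates 10 episodes of 46 s per firing-rate condition
(1, 5, 10 Hz) with the full 1024-input population, pools sweeps across
episodes, and runs the bootstrap at 50 sets × 50 repetitions on the cells
whose pools exceed 10·N; generator statistics use 200 trains × 200 s and
10⁶ amplitude draws. These sizes give Monte-Carlo errors well inside the
asserted tolerances while keeping a laptop-scale run.
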