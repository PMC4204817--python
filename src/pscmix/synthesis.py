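"""Injectable current waveform synthesis.

Two paradigms are supported.  In the *signal-immersed-in-noise* paradigm the
current is the sum of three components: an Ornstein–Uhlenbeck (OU) background
with SD ``sigma`` and correlation time ``tau_corr``, a periodic train of
artificial PSCs (the "signal"), and a DC offset.  In the *fully-defined
mixture* paradigm the fluctuating current is the superposition of PSC trains
from every neuron of a model presynaptic population (excitatory positive,
inhibitory negative), globally rescaled to a target SD; because every PSC
onset is known, any input's PSCs can be treated as signal and the rest as
noise.

PSC waveforms are difference-of-two-exponentials kernels normalized to unit
peak, so a neuron's "amplitude" in pA is exactly the peak current of its PSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sps

from .population import PresynapticPopulation, SpikeTrain

__all__ = [
    "PSCKernel",
    "OUSpec",
    "CurrentTrace",
    "make_kernel",
    "generate_ou",
    "render_psc_train",
    "synthesize_signal_in_noise",
    "synthesize_mixture",
    "trigger_table",
]

#: columns of a trigger table (one row per presynaptic spike)
TRIGGER_COLUMNS = ("neuron_id", "sign", "amplitude_pA", "amplitude_class", "onset_time_s")


@dataclass(frozen=True)
class PSCKernel:
    """Unit-peak difference-of-exponentials PSC template.

    ``w(t) ∝ exp(-t/tau_decay) - exp(-t/tau_rise)``, normalized so the peak
    equals 1 and ``w(0) = 0``.  The waveform is truncated where it falls
    below ``1e-4`` of the peak (~9 decay time constants).
    """

    tau_rise: float  # ms
    tau_decay: float  # ms
    dt: float  # ms
    waveform: np.ndarray = field(repr=False)

    @property
    def kernel_length(self) -> float:
        """Truncated kernel support in ms."""
        return self.waveform.size * self.dt

    @property
    def peak_time(self) -> float:
        """Analytic time-to-peak in ms."""
        r, d = self.tau_rise, self.tau_decay
        return r * d / (d - r) * np.log(d / r)


@dataclass(frozen=True)
class OUSpec:
    """Ornstein–Uhlenbeck background-noise parameters (SD in pA, times in ms)."""

    sigma: float
    tau_corr: float = 5.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.tau_corr <= 0:
            raise ValueError(f"tau_corr must be > 0, got {self.tau_corr}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")


@dataclass
class CurrentTrace:
    """Uniformly sampled current waveform (pA) plus provenance metadata."""

    samples: np.ndarray
    dt: float  # ms
    dc_offset: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size * self.dt / 1000.0

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) * self.dt / 1000.0


def _n_samples(duration_s: float, dt_ms: float) -> int:
    return int(round(duration_s * 1000.0 / dt_ms))


def make_kernel(tau_rise: float, tau_decay: float, dt: float = 0.05, cutoff: float = 1e-4) -> PSCKernel:
    """Build the unit-peak difference-of-exponentials PSC kernel."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError(f"need 0 < tau_rise < tau_decay, got ({tau_rise}, {tau_decay})")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    # support: after the peak only the decay exponential matters
    t_end = t_peak + tau_decay * np.log(1.0 / (cutoff * peak))
    t = np.arange(_n_samples(t_end / 1000.0, dt) + 2) * dt
    w = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    w /= w.max()  # normalize to the on-grid peak so amplitude == rendered peak
    last = int(np.nonzero(w >= cutoff)[0][-1])  # tail beyond this is < cutoff
    return PSCKernel(tau_rise, tau_decay, dt, w[: last + 2])


def generate_ou(spec: OUSpec, duration: float, seed: int | np.random.Generator) -> CurrentTrace:
    """Generate a stationary OU trace by the exact discretization.

    ``x[n+1] = x[n] * a + sigma * sqrt(1 - a^2) * xi[n]`` with
    ``a = exp(-dt/tau)`` and ``x[0] ~ N(0, sigma^2)``, which is exact for any
    step size.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = _n_samples(duration, spec.dt)
    if spec.sigma == 0.0:
        return CurrentTrace(np.zeros(n), spec.dt, meta={"component": "ou", "sigma": 0.0})
    a = np.exp(-spec.dt / spec.tau_corr)
    noise = rng.standard_normal(n) * (spec.sigma * np.sqrt(1.0 - a * a))
    noise[0] = rng.standard_normal() * spec.sigma  # stationary start
    # x[n] = sum_{m<=n} a^(n-m) noise[m]  — an IIR filter with pole at a
    x = sps.lfilter([1.0], [1.0, -a], noise)
    return CurrentTrace(x, spec.dt, meta={"component": "ou", "sigma": spec.sigma, "tau_corr": spec.tau_corr})


def _delta_train(onsets_s: np.ndarray, weights: np.ndarray, n: int, dt: float) -> np.ndarray:
    """Sum of weighted deltas on the sample grid (onsets snapped to nearest sample)."""
    idx = np.rint(np.asarray(onsets_s) * 1000.0 / dt).astype(np.int64)
    keep = (idx >= 0) & (idx < n)
    out = np.zeros(n)
    np.add.at(out, idx[keep], np.asarray(weights)[keep])
    return out


def render_psc_train(
    kernel: PSCKernel,
    onsets: SpikeTrain | np.ndarray,
    amplitude: float,
    duration: float,
) -> CurrentTrace:
    """Superpose ``amplitude * w(t - onset)`` over all onsets (linear)."""
    times = onsets.times if isinstance(onsets, SpikeTrain) else np.asarray(onsets, dtype=float)
    n = _n_samples(duration, kernel.dt)
    deltas = _delta_train(times, np.full(times.size, amplitude), n, kernel.dt)
    out = sps.fftconvolve(deltas, kernel.waveform)[:n] if times.size else np.zeros(n)
    return CurrentTrace(out, kernel.dt, meta={"component": "psc_train"})


def trigger_table(pop: PresynapticPopulation, scale_factor: float = 1.0) -> pd.DataFrame:
    """One row per presynaptic spike: the ground-truth signal onsets."""
    frames = []
    for nrn in pop.neurons:
        if len(nrn.train) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "neuron_id": nrn.neuron_id,
                    "sign": nrn.sign,
                    "amplitude_pA": nrn.amplitude * scale_factor,
                    "amplitude_class": nrn.amplitude_class,
                    "onset_time_s": nrn.train.times,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=list(TRIGGER_COLUMNS))
    return pd.concat(frames, ignore_index=True)[list(TRIGGER_COLUMNS)]


def synthesize_signal_in_noise(
    ou: OUSpec,
    signal_kernel: PSCKernel,
    signal_amplitude: float,
    signal_onsets: SpikeTrain,
    dc: float,
    duration: float,
    seed: int | np.random.Generator,
) -> tuple[CurrentTrace, pd.DataFrame]:
    """Paradigm 1: OU noise + one artificial PSC train + DC.

    Returns the summed trace and a trigger table holding the signal onsets
    (sign follows the sign of ``signal_amplitude``).
    """
    ou_trace = generate_ou(ou, duration, seed)
    sig = render_psc_train(signal_kernel, signal_onsets, signal_amplitude, duration)
    samples = ou_trace.samples + sig.samples + dc
    trace = CurrentTrace(
        samples,
        ou.dt,
        dc_offset=dc,
        meta={
            "paradigm": "signal_in_noise",
            "sigma": ou.sigma,
            "signal_amplitude": signal_amplitude,
            "dc": dc,
        },
    )
    triggers = pd.DataFrame(
        {
            "neuron_id": 0,
            "sign": "excitatory" if signal_amplitude >= 0 else "inhibitory",
            "amplitude_pA": abs(signal_amplitude),
            "amplitude_class": 0,
            "onset_time_s": signal_onsets.times,
        }
    )[list(TRIGGER_COLUMNS)]
    return trace, triggers


def synthesize_mixture(
    pop: PresynapticPopulation,
    kernel: PSCKernel,
    target_sd: float,
    dc: float,
    duration: float | None = None,
) -> tuple[CurrentTrace, pd.DataFrame, float]:
    """Paradigm 2: summed PSC trains of the whole population, scaled to target SD.

    Excitatory PSCs enter positive, inhibitory negative.  The zero-DC sum is
    globally rescaled so its sample SD equals ``target_sd`` (pA); DC is added
    afterwards.  Returns (trace, trigger table, scale factor); trigger-table
    amplitudes are post-scaling, so they are directly expressible in units of
    ``target_sd``.
    """
    if pop.n_total == 0:
        raise ValueError("empty population")
    if duration is None:
        duration = pop.renewal.duration
    n = _n_samples(duration, kernel.dt)
    # all neurons superposed in one signed delta train, convolved once with
    # the shared kernel — identical to per-neuron rendering by linearity
    onsets = np.concatenate([nrn.train.times for nrn in pop.neurons])
    weights = np.concatenate(
        [
            np.full(len(nrn.train), nrn.amplitude if nrn.sign == "excitatory" else -nrn.amplitude)
            for nrn in pop.neurons
        ]
    )
    deltas = _delta_train(onsets, weights, n, kernel.dt)
    raw = sps.fftconvolve(deltas, kernel.waveform)[:n]
    raw_sd = float(raw.std())
    if raw_sd == 0.0:
        raise ValueError("population produced a flat current; cannot scale to target SD")
    scale = target_sd / raw_sd
    trace = CurrentTrace(
        raw * scale + dc,
        kernel.dt,
        dc_offset=dc,
        meta={
            "paradigm": "mixture",
            "target_sd": target_sd,
            "scale_factor": scale,
            "dc": dc,
            "seed": pop.seed,
        },
    )
    return trace, trigger_table(pop, scale), scale
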