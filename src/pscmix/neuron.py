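"""Model postsynaptic neuron: a calibrated stand-in for the patch-clamped cell.

A leaky integrate-and-fire (LIF) neuron, optionally with an exponential
spike-initiation term, converts injected-current traces into membrane
potential and spike times.  Default parameters are textbook
cortical-pyramidal values, with the input resistance chosen so that a
fluctuating current of SD 70–110 pA evokes membrane-potential fluctuations
of 15–20 mV (5th–95th percentile range), emulating the in-vivo-like regime
of the recorded layer-2/3 cell.  No claim of quantitative equivalence to any
real neuron is made.

Because an integrate-and-fire model has no action-potential overshoot, a
stylized spike waveform (2 ms triangular excursion to +30 mV) is pasted into
the returned voltage trace at each registered spike, so that the
positive-zero-crossing spike-detection rule used for real recordings can be
exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .population import PresynapticPopulation
from .synthesis import CurrentTrace, PSCKernel, synthesize_mixture

__all__ = [
    "NeuronParams",
    "Episode",
    "EpisodeSet",
    "simulate",
    "detect_spikes",
    "firing_rate",
    "calibrate_dc",
    "run_episodes",
]


@dataclass(frozen=True)
class NeuronParams:
    """Integrate-and-fire parameters (times ms, voltages mV, resistance MΩ)."""

    tau_m: float = 20.0
    r_in: float = 130.0
    v_rest: float = -70.0
    v_threshold: float = -50.0
    v_reset: float = -60.0
    t_refractory: float = 2.0
    delta_t: float | None = None  # exponential spike-initiation sharpness, mV

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.r_in <= 0 or self.t_refractory < 0:
            raise ValueError("time constants and resistance must be positive")
        if self.v_threshold <= self.v_reset:
            raise ValueError("threshold must exceed reset")
        if self.delta_t is not None and self.delta_t <= 0:
            raise ValueError("delta_t must be > 0 when given")


@njit(cache=True)
def _integrate(
    current: np.ndarray,
    dt: float,
    tau_m: float,
    r_in: float,
    v_rest: float,
    v_th: float,
    v_reset: float,
    n_ref: int,
    delta_t: float,
) -> tuple[np.ndarray, np.ndarray]:
    # exponential Euler for the leak (current held constant over each step);
    # the optional exponential spike term enters as a forward-Euler current.
    n = current.size
    v = np.empty(n)
    spikes = np.empty(n, dtype=np.int64)
    n_spikes = 0
    decay = np.exp(-dt / tau_m)
    vm = v_rest
    ref = 0
    cut = v_th + 30.0 if delta_t > 0.0 else v_th
    for i in range(n):
        if ref > 0:
            ref -= 1
            vm = v_reset
        else:
            v_inf = v_rest + r_in * current[i] * 1e-3  # pA * MΩ = 1e-3 mV
            vm = v_inf + (vm - v_inf) * decay
            if delta_t > 0.0:
                vm += (dt / tau_m) * delta_t * np.exp((vm - v_th) / delta_t)
            if vm >= cut:
                spikes[n_spikes] = i
                n_spikes += 1
                vm = v_reset
                ref = n_ref
        v[i] = vm
    return v, spikes[:n_spikes]


def _paste_spike_shapes(v: np.ndarray, spike_idx: np.ndarray, dt: float, v_reset: float) -> None:
    # 2 ms triangular overshoot to +30 mV so zero-crossing detection works
    half = max(1, int(round(1.0 / dt)))
    n = v.size
    ramp_up = np.linspace(0.0, 1.0, half + 1)[1:]
    for s in spike_idx:
        base = v[s - 1] if s > 0 else v_reset
        up_end = min(s + half, n)
        v[s:up_end] = base + (30.0 - base) * ramp_up[: up_end - s]
        down_end = min(s + 2 * half, n)
        if down_end > up_end:
            v[up_end:down_end] = 30.0 + (v_reset - 30.0) * ramp_up[: down_end - up_end]


def simulate(
    params: NeuronParams, current: CurrentTrace, paste_spikes: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the model neuron; return (voltage mV, spike times s).

    Deterministic given its inputs (the model itself is noiseless; all
    stochasticity lives in the injected current).  Spikes are registered at
    threshold crossing with voltage reset and an absolute refractory period.
    """
    samples = np.ascontiguousarray(current.samples, dtype=np.float64)
    if not np.isfinite(samples).all():
        raise ValueError("current trace contains non-finite samples")
    dt = current.dt
    v, spike_idx = _integrate(
        samples,
        dt,
        params.tau_m,
        params.r_in,
        params.v_rest,
        params.v_threshold,
        params.v_reset,
        int(round(params.t_refractory / dt)),
        0.0 if params.delta_t is None else params.delta_t,
    )
    if paste_spikes and spike_idx.size:
        _paste_spike_shapes(v, spike_idx, dt, params.v_reset)
    return v, spike_idx * dt / 1000.0


def detect_spikes(voltage: np.ndarray, dt: float, threshold: float = 0.0) -> np.ndarray:
    """Spike times (s) as positive crossings of ``threshold`` (default 0 mV)."""
    v = np.asarray(voltage)
    up = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    return up * dt / 1000.0


def firing_rate(spike_times: np.ndarray, duration: float, discard: float = 0.0) -> float:
    """Mean rate (Hz) over [discard, duration]."""
    kept = np.asarray(spike_times)
    kept = kept[kept >= discard]
    return kept.size / (duration - discard)


def calibrate_dc(
    params: NeuronParams,
    template_current: CurrentTrace,
    target_rate: float,
    tol: float | None = None,
    discard: float = 2.0,
    dc_bracket: tuple[float, float] = (-200.0, 600.0),
    max_steps: int = 10,
) -> float:
    """Bisect the DC offset until the probe firing rate hits the target.

    The probe is the template current plus a candidate DC; the rate excludes
    the initial ``discard`` window.  Tolerance defaults to 5% of the target.
    For ``target_rate = 0`` the lower bracket edge is returned if it
    silences the cell.
    """
    if tol is None:
        tol = 0.05 * max(target_rate, 1e-9)
    duration = template_current.duration

    def rate_at(dc: float) -> float:
        probe = CurrentTrace(template_current.samples + dc, template_current.dt)
        _, st = simulate(params, probe, paste_spikes=False)
        return firing_rate(st, duration, discard)

    lo, hi = dc_bracket
    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if target_rate == 0.0:
        if r_lo == 0.0:
            return lo
        raise RuntimeError(f"cannot silence neuron within bracket (rate {r_lo:.2f} Hz at {lo} pA)")
    if not (r_lo <= target_rate <= r_hi):
        raise RuntimeError(
            f"target {target_rate} Hz outside achievable bracket [{r_lo:.2f}, {r_hi:.2f}] Hz"
        )
    dc = (lo + hi) / 2.0
    for _ in range(max_steps):
        dc = (lo + hi) / 2.0
        r = rate_at(dc)
        if abs(r - target_rate) <= tol:
            return dc
        if r < target_rate:
            lo = dc
        else:
            hi = dc
    return dc


@dataclass
class Episode:
    """One current-injection episode: spikes, triggers, optional traces."""

    episode_id: int
    spike_times: np.ndarray  # s, all spikes including the discard window
    triggers: "object"  # pandas DataFrame, TRIGGER_COLUMNS
    dc: float
    current: CurrentTrace | None = None
    voltage: np.ndarray | None = None


@dataclass
class EpisodeSet:
    """Episodes plus the protocol constants the analysis needs."""

    episodes: list[Episode]
    duration: float  # s
    discard: float  # s
    dt: float  # ms
    meta: dict = field(default_factory=dict)

    def analyzed_spikes(self, episode: Episode) -> np.ndarray:
        return episode.spike_times[episode.spike_times >= self.discard]

    def rate_in_bins(self, bin_s: float = 5.0) -> np.ndarray:
        """Per-episode firing rate in consecutive bins (episodes x bins), Hz."""
        edges = np.arange(0.0, self.duration + 1e-9, bin_s)
        return np.vstack(
            [np.histogram(ep.spike_times, bins=edges)[0] / bin_s for ep in self.episodes]
        )


def run_episodes(
    params: NeuronParams,
    pop: PresynapticPopulation,
    kernel: PSCKernel,
    n_episodes: int,
    target_sd: float = 100.0,
    dc: float | None = None,
    target_rate: float = 5.0,
    duration: float = 46.0,
    discard: float = 2.0,
    keep_traces: bool = False,
) -> EpisodeSet:
    """Simulate the episode protocol of the mixture paradigm.

    Each episode uses a fresh spike-train realization of the same population
    roster (per-episode RNG substreams) and the same DC.  If ``dc`` is None
    it is first calibrated on episode 0's current to ``target_rate``.
    """
    episodes: list[Episode] = []
    pops = [pop.with_new_spikes(ep + 1) for ep in range(n_episodes)]
    if dc is None:
        template, _, _ = synthesize_mixture(pops[0], kernel, target_sd, 0.0, duration)
        dc = calibrate_dc(params, template, target_rate, discard=discard)
    for ep, ep_pop in enumerate(pops):
        current, triggers, _ = synthesize_mixture(ep_pop, kernel, target_sd, dc, duration)
        voltage, spike_times = simulate(params, current)
        episodes.append(
            Episode(
                ep,
                spike_times,
                triggers,
                dc,
                current if keep_traces else None,
                voltage if keep_traces else None,
            )
        )
    return EpisodeSet(
        episodes,
        duration,
        discard,
        kernel.dt,
        meta={"dc": dc, "target_sd": target_sd, "seed": pop.seed, "target_rate": target_rate},
    )
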