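"""Run configuration: one self-validating object covering both paradigms."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import yaml

from .neuron import NeuronParams
from .population import AmplitudeDistribution, RenewalSpec

__all__ = ["RunConfig", "default_mixture_config", "default_signal_in_noise_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run one experiment deterministically.

    Units: ms for kernel time constants and analysis windows, s for
    durations, pA for currents, Hz for rates.
    """

    paradigm: Literal["signal_in_noise", "mixture"] = "mixture"
    seed: int = 0
    # population (mixture) / signal train (signal-in-noise)
    n_population: int = 1024
    e_fraction: float = 0.5
    renewal: RenewalSpec = field(default_factory=RenewalSpec)
    amplitudes: AmplitudeDistribution = field(default_factory=AmplitudeDistribution)
    stratified_amplitudes: bool = False
    # PSC kernel; paradigm-1 default is (1, 10) ms, paradigm-2 (0.5, 5) ms
    tau_rise: float = 0.5
    tau_decay: float = 5.0
    dt: float = 0.05
    # current scaling
    target_sd: float = 100.0  # mixture: global SD of the fluctuating current
    ou_sigma: float = 110.0  # signal-in-noise: OU noise SD
    ou_tau: float = 5.0
    signal_amplitude: float = 50.0  # signal-in-noise: aPSC peak, pA
    # protocol
    n_episodes: int = 20
    episode_duration: float = 46.0
    discard: float = 2.0
    target_rate: float = 5.0
    dc: float | None = None  # None -> calibrate to target_rate
    neuron: NeuronParams = field(default_factory=NeuronParams)
    # analysis
    t_max: float = 15.0
    t_grid: tuple[float, ...] = tuple(round(0.4 * i, 10) for i in range(1, 38))
    n_list: tuple[int, ...] = (250, 500, 1000, 2000)
    alpha: float = 0.05
    method: Literal["parametric", "bootstrap", "both"] = "parametric"
    bootstrap_sets: int = 100
    bootstrap_reps: int = 100
    psth_bin: float = 0.5

    def __post_init__(self) -> None:
        if self.paradigm not in ("signal_in_noise", "mixture"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.n_episodes < 1 or self.episode_duration <= 0:
            raise ValueError("need at least one episode of positive duration")
        if not 0.0 <= self.e_fraction <= 1.0:
            raise ValueError("e_fraction must lie in [0, 1]")
        if self.discard >= self.episode_duration:
            raise ValueError("discard window must be shorter than the episode")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "renewal" in data and isinstance(data["renewal"], dict):
            data["renewal"] = RenewalSpec(**data["renewal"])
        if "amplitudes" in data and isinstance(data["amplitudes"], dict):
            data["amplitudes"] = AmplitudeDistribution(**data["amplitudes"])
        if "neuron" in data and isinstance(data["neuron"], dict):
            data["neuron"] = NeuronParams(**data["neuron"])
        for key in ("t_grid", "n_list"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_mixture_config(seed: int = 0, **overrides) -> RunConfig:
    """The fully-defined mixture defaults: 1024 inputs (512 E / 512 I),
    32 log-normal amplitude classes, SD 100 pA, 46 s episodes at 5 Hz."""
    return replace(RunConfig(seed=seed), **overrides)


def default_signal_in_noise_config(seed: int = 0, **overrides) -> RunConfig:
    """Signal-immersed-in-noise defaults: one 50 pA aEPSC train at ~5 Hz in
    OU noise of SD 110 pA, kernel time constants (1, 10) ms."""
    cfg = RunConfig(
        paradigm="signal_in_noise",
        seed=seed,
        tau_rise=1.0,
        tau_decay=10.0,
        ou_sigma=110.0,
        signal_amplitude=50.0,
        n_list=(250, 500, 1000, 2000),
    )
    return replace(cfg, **overrides)
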