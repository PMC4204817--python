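"""Shared fixtures: small model-neuron runs reused across test modules.

The session-scoped runs emulate the episode protocol (46 s episodes, 2 s
discard, 1024 presynaptic inputs, injected-current SD 100 pA) at three
postsynaptic firing rates, 10 episodes per rate.
"""

from __future__ import annotations

import numpy as np
import pytest

import pscmix as pm

MASTER_SEED = 20240928
N_EPISODES = 10
TARGET_SD = 100.0
RATES = (1.0, 5.0, 10.0)


@pytest.fixture(scope="session")
def mixture_kernel() -> pm.PSCKernel:
    return pm.make_kernel(0.5, 5.0, 0.05)


@pytest.fixture(scope="session")
def population(mixture_kernel) -> pm.PresynapticPopulation:
    return pm.build_population(
        1024, 0.5, pm.RenewalSpec(duration=46.0), pm.AmplitudeDistribution(), MASTER_SEED
    )


@pytest.fixture(scope="session")
def model_runs(population, mixture_kernel) -> dict[float, pm.EpisodeSet]:
    """Episode sets of the mixture paradigm at 1, 5 and 10 Hz."""
    runs = {}
    for rate in RATES:
        runs[rate] = pm.run_episodes(
            pm.NeuronParams(),
            population,
            mixture_kernel,
            N_EPISODES,
            target_sd=TARGET_SD,
            target_rate=rate,
        )
    return runs


@pytest.fixture(scope="session")
def sweeps_by_rate(model_runs) -> dict[float, pm.TriggeredSweeps]:
    return {rate: pm.collect_sweeps(run, 15.0) for rate, run in model_runs.items()}


@pytest.fixture(scope="session")
def sweeps_5hz(sweeps_by_rate) -> pm.TriggeredSweeps:
    return sweeps_by_rate[5.0]
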