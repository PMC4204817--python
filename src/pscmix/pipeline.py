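"""End-to-end experiment driver: synthesis -> model neuron -> detection.

``run_experiment`` executes either paradigm from a single :class:`RunConfig`
and writes a self-contained artifact bundle (roster, spikes, triggers,
PSTHs, detection surfaces, plots, and a JSON log of seeds and calibration)
so the analysis half can be re-run from the saved CSVs without
re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .detection import TriggeredSweeps, build_psth, collect_sweeps, detection_surface
from .neuron import Episode, EpisodeSet, calibrate_dc, run_episodes, simulate
from .population import build_population
from .synthesis import CurrentTrace, make_kernel, synthesize_mixture, synthesize_signal_in_noise
from .population import RenewalSpec, sample_renewal_train

__all__ = ["run_experiment", "simulate_episodes", "analyze_episodes", "analyze_saved"]


def simulate_episodes(config: RunConfig) -> EpisodeSet:
    """Run the protocol of the configured paradigm; return the episode set."""
    kernel = make_kernel(config.tau_rise, config.tau_decay, config.dt)
    if config.paradigm == "mixture":
        pop = build_population(
            config.n_population,
            config.e_fraction,
            config.renewal,
            config.amplitudes,
            config.seed,
            config.stratified_amplitudes,
        )
        return run_episodes(
            config.neuron,
            pop,
            kernel,
            config.n_episodes,
            target_sd=config.target_sd,
            dc=config.dc,
            target_rate=config.target_rate,
            duration=config.episode_duration,
            discard=config.discard,
        )
    # signal-immersed-in-noise: fresh OU noise and fresh signal-onset train
    # per episode, fixed DC calibrated on episode 0
    from .synthesis import OUSpec

    ou = OUSpec(config.ou_sigma, config.ou_tau, config.dt)
    renewal = replace(config.renewal, duration=config.episode_duration)
    dc = config.dc
    episodes: list[Episode] = []
    for ep in range(config.n_episodes):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51, ep]))
        onsets = sample_renewal_train(renewal, rng)
        trace, triggers = synthesize_signal_in_noise(
            ou,
            kernel,
            config.signal_amplitude,
            onsets,
            0.0,
            config.episode_duration,
            rng,
        )
        if dc is None:
            dc = calibrate_dc(config.neuron, trace, config.target_rate, discard=config.discard)
        trace = CurrentTrace(trace.samples + dc, trace.dt, dc, trace.meta)
        _, spike_times = simulate(config.neuron, trace)
        episodes.append(Episode(ep, spike_times, triggers, dc))
    return EpisodeSet(
        episodes,
        config.episode_duration,
        config.discard,
        config.dt,
        meta={"dc": dc, "sigma": config.ou_sigma, "seed": config.seed},
    )


def analyze_episodes(config: RunConfig, episodes: EpisodeSet) -> dict[str, pd.DataFrame]:
    """Sweep collection, PSTHs and detection surfaces for an episode set."""
    sweeps = collect_sweeps(episodes, config.t_max)
    sd = config.target_sd if config.paradigm == "mixture" else config.ou_sigma
    methods = ["parametric", "bootstrap"] if config.method == "both" else [config.method]
    surfaces = []
    for method in methods:
        surfaces.append(
            detection_surface(
                sweeps,
                config.t_grid,
                config.n_list,
                method=method,
                alpha=config.alpha,
                sd_pA=sd,
                rate_hz=config.target_rate,
                n_sets=config.bootstrap_sets,
                n_reps=config.bootstrap_reps,
                seed=config.seed,
            )
        )
    psths = []
    for key in sweeps.keys():
        psth = build_psth(sweeps.groups[key], config.psth_bin)
        psth.insert(0, "sign", key[0])
        psth.insert(1, "amplitude_class", key[1])
        psths.append(psth)
    return {"surface": pd.concat(surfaces, ignore_index=True), "psth": pd.concat(psths, ignore_index=True)}


def run_experiment(config: RunConfig, outdir: str | Path, plots: bool = True) -> dict:
    """Execute the full pipeline and write the artifact bundle to ``outdir``.

    Returns a summary dict (paths, DC, per-episode rates).  Deterministic
    given ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    stamp = {"config_hash": pio.config_hash(cfg_dict), "seed": config.seed}
    config.to_yaml(outdir / "config.yaml")

    episodes = simulate_episodes(config)
    trig_all = []
    for ep in episodes.episodes:
        t = ep.triggers.copy()
        t.insert(0, "episode_id", ep.episode_id)
        trig_all.append(t)
    pd.concat(trig_all, ignore_index=True).to_csv(outdir / "triggers.csv", index=False)
    pio.write_spikes_csv(
        {ep.episode_id: ep.spike_times for ep in episodes.episodes}, outdir / "spikes.csv"
    )
    results = analyze_episodes(config, episodes)
    results["surface"].to_csv(outdir / "detection_surface.csv", index=False)
    results["psth"].to_csv(outdir / "psth.csv", index=False)

    rates = episodes.rate_in_bins(5.0)
    log = {
        **stamp,
        "paradigm": config.paradigm,
        "dc_pA": episodes.meta.get("dc"),
        "episode_rates_hz": [float(r) for r in rates.mean(axis=1)],
        "mean_rate_hz": float(rates.mean()),
        "n_episodes": len(episodes.episodes),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))

    if plots:
        from .plots import plot_detection_heatmaps, plot_psth

        plot_detection_heatmaps(results["surface"], outdir / "detection_heatmaps.png")
        plot_psth(results["psth"], outdir / "psth.png")
    return log


def analyze_saved(
    spikes_csv: str | Path,
    triggers_csv: str | Path,
    config: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Re-run the analysis half from saved spike + trigger CSVs.

    This is also the entry point for externally recorded data: any spike
    table (episode_id, time_s) and trigger table with matching episode ids
    can be analyzed without the simulator.
    """
    spikes = pio.read_spikes_csv(spikes_csv)
    trig = pd.read_csv(triggers_csv)
    episodes = [
        Episode(int(ep_id), np.sort(spikes.get(int(ep_id), np.empty(0))), g.drop(columns="episode_id"), 0.0)
        for ep_id, g in trig.groupby("episode_id")
    ]
    epset = EpisodeSet(episodes, config.episode_duration, config.discard, config.dt)
    return analyze_episodes(config, epset)
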