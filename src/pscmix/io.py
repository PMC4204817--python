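"""Readers and writers for traces, triggers and spikes.

Formats: single-column CSV and raw little-endian float32 (with a JSON
sidecar carrying dt, units and provenance) for current traces; Axon Text
File (ATF) export so synthesized waveforms can drive acquisition software;
CSV for trigger tables and spike times.  Units are declared in file headers:
ms for kernel/window parameters, s for spike and onset times, pA for
currents, mV for voltages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthesis import CurrentTrace, TRIGGER_COLUMNS

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_float32",
    "read_trace_float32",
    "write_trace_atf",
    "write_triggers_csv",
    "read_triggers_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "config_hash",
]


def _sidecar(trace: CurrentTrace) -> dict:
    return {
        "dt_ms": trace.dt,
        "n_samples": int(trace.samples.size),
        "units": "pA",
        "dc_offset_pA": trace.dc_offset,
        "meta": {k: v for k, v in trace.meta.items() if isinstance(v, (int, float, str, bool))},
    }


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> None:
    path = Path(path)
    header = "# current_pA, dt_ms=%r, dc_offset_pA=%r\ncurrent_pA\n" % (trace.dt, trace.dc_offset)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, trace.samples, fmt="%.6f")


def read_trace_csv(path: str | Path) -> CurrentTrace:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    dt = float(header.split("dt_ms=")[1].split(",")[0])
    dc = float(header.split("dc_offset_pA=")[1].strip())
    samples = np.loadtxt(path, skiprows=2)
    return CurrentTrace(samples, dt, dc)


def write_trace_float32(trace: CurrentTrace, path: str | Path) -> None:
    """Raw little-endian float32 samples + <path>.json sidecar."""
    path = Path(path)
    trace.samples.astype("<f4").tofile(path)
    Path(str(path) + ".json").write_text(json.dumps(_sidecar(trace), indent=2))


def read_trace_float32(path: str | Path) -> CurrentTrace:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    samples = np.fromfile(path, dtype="<f4").astype(float)
    return CurrentTrace(samples, sidecar["dt_ms"], sidecar["dc_offset_pA"], sidecar.get("meta", {}))


def write_trace_atf(trace: CurrentTrace, path: str | Path, title: str = "pscmix waveform") -> None:
    """Minimal Axon Text File (ATF 1.0): time (ms) and current (pA) columns."""
    path = Path(path)
    t_ms = np.arange(trace.samples.size) * trace.dt
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write("2\t2\n")
        fh.write(f'"Comment={title}"\n')
        fh.write(f'"SampleInterval={trace.dt} ms"\n')
        fh.write('"Time (ms)"\t"Current (pA)"\n')
        np.savetxt(fh, np.column_stack([t_ms, trace.samples]), fmt="%.6f", delimiter="\t")


def write_triggers_csv(triggers: pd.DataFrame, path: str | Path) -> None:
    triggers[list(TRIGGER_COLUMNS)].to_csv(path, index=False)


def read_triggers_csv(path: str | Path) -> pd.DataFrame:
    trig = pd.read_csv(path)
    missing = set(TRIGGER_COLUMNS) - set(trig.columns)
    if missing:
        raise ValueError(f"trigger table missing columns: {sorted(missing)}")
    return trig


def write_spikes_csv(spikes_by_episode: dict[int, np.ndarray], path: str | Path) -> None:
    """Postsynaptic spike output: columns (episode_id, time_s)."""
    frames = [
        pd.DataFrame({"episode_id": ep, "time_s": np.asarray(times)})
        for ep, times in sorted(spikes_by_episode.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spikes_csv(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {int(ep): g["time_s"].to_numpy() for ep, g in df.groupby("episode_id")}


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance stamps."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
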