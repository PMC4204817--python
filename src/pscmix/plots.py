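"""Publication-style figures: detection heatmaps, amplitude slices, PSTHs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_detection_heatmaps", "plot_detection_slices", "plot_psth"]


def plot_detection_heatmaps(surface: pd.DataFrame, path: str | Path, n: int | None = None) -> None:
    """Detection probability vs (T, amplitude) heatmap, one panel per sign."""
    df = surface[surface["method"] == "parametric"] if "method" in surface else surface
    if n is None:
        n = int(df["N"].max())
    df = df[df["N"] == n]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), constrained_layout=True)
    for ax, sign in zip(axes, ("excitatory", "inhibitory")):
        sub = df[df["sign"] == sign]
        if sub.empty:
            ax.set_axis_off()
            continue
        pivot = sub.pivot_table(index="amplitude_sd_units", columns="T_ms", values="detection_prob")
        im = ax.pcolormesh(
            pivot.columns.to_numpy(),
            pivot.index.to_numpy(),
            pivot.to_numpy(),
            vmin=0,
            vmax=1,
            cmap="viridis",
            shading="nearest",
        )
        ax.set_xlabel("T after onset (ms)")
        ax.set_ylabel("amplitude (units of current SD)")
        ax.set_title(f"{sign} aPSCs, N = {n}")
    fig.colorbar(im, ax=axes, label="detection probability")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_detection_slices(surface: pd.DataFrame, path: str | Path, t_ms: float = 5.0) -> None:
    """Detection vs amplitude at fixed T, one curve per (sign, N, method)."""
    df = surface[np.isclose(surface["T_ms"], t_ms)]
    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    for (sign, n, method), sub in df.groupby(["sign", "N", "method"]):
        sub = sub.sort_values("amplitude_sd_units")
        style = "-" if method == "parametric" else "--o"
        ax.plot(
            sub["amplitude_sd_units"],
            sub["detection_prob"],
            style,
            ms=3,
            label=f"{sign[0].upper()} N={n} {method}",
        )
    ax.set_xlabel("amplitude (units of current SD)")
    ax.set_ylabel(f"detection probability within {t_ms:g} ms")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psth(psth: pd.DataFrame, path: str | Path, max_panels: int = 8) -> None:
    """Onset-triggered firing-rate histograms for the largest-amplitude classes."""
    keys = (
        psth.groupby(["sign", "amplitude_class"])
        .size()
        .reset_index()[["sign", "amplitude_class"]]
        .sort_values("amplitude_class", ascending=False)
        .head(max_panels)
    )
    fig, ax = plt.subplots(figsize=(6, 4), constrained_layout=True)
    for sign, cls in keys.itertuples(index=False):
        sub = psth[(psth["sign"] == sign) & (psth["amplitude_class"] == cls)]
        ax.plot(sub["time_ms"], sub["rate_hz"], label=f"{sign[0].upper()} class {cls}", lw=1)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time from PSC onset (ms)")
    ax.set_ylabel("firing rate (Hz)")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=150)
    plt.close(fig)
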