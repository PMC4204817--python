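"""Detectability of single PSCs from population firing.

Every presynaptic PSC onset is a trigger.  Postsynaptic spikes are aligned to
the triggers ("sweeps"), grouped by the input's sign and amplitude class, and
summarized two ways:

* a peri-stimulus time histogram (PSTH) of firing rate around onset, and
* window spike probabilities ``P_pre`` / ``P_post`` — the probability of at
  least one spike in the length-``T`` window immediately before / after the
  onset.

A hypothetical downstream decoder observes the summed spike count of ``N``
statistically identical transmitting neurons (modeled by N independent
sweeps) and declares a signal when the post-onset count exceeds the 95%
quantile (excitatory) or falls below the 5% quantile (inhibitory) of the
pre-signal count distribution.  Detection probability is computed either
parametrically — both counts modeled as binomials ``B(N, P_post)`` vs
``B(N, P_pre)`` — or by bootstrap resampling of sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .neuron import EpisodeSet

__all__ = [
    "SweepGroup",
    "TriggeredSweeps",
    "WindowProbs",
    "collect_sweeps",
    "build_psth",
    "window_probs",
    "parametric_detection",
    "bootstrap_detection",
    "detection_surface",
    "shift_triggers",
]

Sign = Literal["excitatory", "inhibitory"]


@dataclass
class SweepGroup:
    """Sweeps for one (sign, amplitude class): spike times relative to onsets.

    Ragged storage: ``rel_times_ms[i]`` is a relative spike time (ms, within
    ±T_max) belonging to sweep ``sweep_index[i]``; sweeps without spikes in
    the window simply have no entries.
    """

    sign: Sign
    amplitude_class: int
    amplitude_pA: float
    n_sweeps: int
    sweep_index: np.ndarray
    rel_times_ms: np.ndarray
    t_max: float  # ms

    def window_counts(self, T: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-sweep spike counts in the pre [-T, 0) and post [0, T) windows."""
        if T <= 0 or T > self.t_max + 1e-9:
            raise ValueError(f"T must be in (0, {self.t_max}] ms, got {T}")
        pre = np.zeros(self.n_sweeps, dtype=np.int64)
        post = np.zeros(self.n_sweeps, dtype=np.int64)
        t = self.rel_times_ms
        in_pre = (t >= -T) & (t < 0.0)
        in_post = (t >= 0.0) & (t < T)
        np.add.at(pre, self.sweep_index[in_pre], 1)
        np.add.at(post, self.sweep_index[in_post], 1)
        return pre, post


@dataclass
class TriggeredSweeps:
    """All sweep groups of one recording, keyed by (sign, amplitude class)."""

    groups: dict[tuple[Sign, int], SweepGroup]
    t_max: float

    def group(self, sign: Sign, amplitude_class: int) -> SweepGroup:
        return self.groups[(sign, amplitude_class)]

    def keys(self) -> list[tuple[Sign, int]]:
        return sorted(self.groups.keys(), key=lambda k: (k[0], k[1]))

    def pooled(self, sign: Sign, classes: Iterable[int] | None = None) -> SweepGroup:
        """Merge groups of one sign (optionally a subset of classes)."""
        keys = [k for k in self.groups if k[0] == sign and (classes is None or k[1] in classes)]
        if not keys:
            raise ValueError(f"no sweep groups for sign {sign!r}")
        parts = [self.groups[k] for k in keys]
        offsets = np.cumsum([0] + [g.n_sweeps for g in parts])
        idx = np.concatenate([g.sweep_index + off for g, off in zip(parts, offsets)])
        rel = np.concatenate([g.rel_times_ms for g in parts])
        mean_amp = float(np.mean([g.amplitude_pA for g in parts]))
        return SweepGroup(sign, -1, mean_amp, int(offsets[-1]), idx, rel, self.t_max)


@dataclass(frozen=True)
class WindowProbs:
    """Window spike probabilities for one group at one T (ms).

    ``p_pre``/``p_post`` are the fractions of sweeps with >= 1 spike in the
    window; ``mean_count_pre``/``mean_count_post`` are the mean spike counts.
    For the short windows used here (< 10 ms at a few Hz) a sweep almost
    never holds two spikes and the two estimators coincide.
    """

    T: float
    p_pre: float
    p_post: float
    n_sweeps: int
    mean_count_pre: float
    mean_count_post: float


def collect_sweeps(
    episodes: EpisodeSet,
    t_max: float = 15.0,
    triggers: Sequence[pd.DataFrame] | None = None,
) -> TriggeredSweeps:
    """Align postsynaptic spikes to PSC onsets, grouped by (sign, class).

    Onsets inside the discard window or closer than ``t_max`` to an episode
    edge are excluded.  ``triggers`` overrides the per-episode trigger tables
    (e.g. for circularly shifted null controls).
    """
    t_max_s = t_max / 1000.0
    acc: dict[tuple[Sign, int], dict] = {}
    for ep in episodes.episodes:
        trig = triggers[ep.episode_id] if triggers is not None else ep.triggers
        spikes = episodes.analyzed_spikes(ep)
        # register every (sign, class) present, so fully excluded groups
        # surface as empty rather than vanish silently
        for sign, cls, amp in (
            trig[["sign", "amplitude_class", "amplitude_pA"]].drop_duplicates().itertuples(index=False)
        ):
            acc.setdefault(
                (sign, int(cls)), {"amp": float(amp), "n": 0, "idx": [], "rel": []}
            )
        onset = trig["onset_time_s"].to_numpy()
        ok = (onset >= max(episodes.discard, t_max_s)) & (onset <= episodes.duration - t_max_s)
        trig = trig.loc[ok]
        onset = onset[ok]
        lo = np.searchsorted(spikes, onset - t_max_s, side="left")
        hi = np.searchsorted(spikes, onset + t_max_s, side="right")
        sign_arr = trig["sign"].to_numpy()
        cls_arr = trig["amplitude_class"].to_numpy()
        amp_arr = trig["amplitude_pA"].to_numpy()
        for key in set(zip(sign_arr, cls_arr)):
            sel = np.nonzero((sign_arr == key[0]) & (cls_arr == key[1]))[0]
            entry = acc.setdefault(
                (key[0], int(key[1])),
                {"amp": float(amp_arr[sel[0]]), "n": 0, "idx": [], "rel": []},
            )
            counts = hi[sel] - lo[sel]
            has = np.nonzero(counts)[0]
            if has.size:
                sweep_ids = entry["n"] + np.repeat(has, counts[has])
                rel = (
                    np.concatenate([spikes[lo[s] : hi[s]] - onset[s] for s in sel[has]]) * 1000.0
                )
                entry["idx"].append(sweep_ids)
                entry["rel"].append(rel)
            entry["n"] += sel.size
    groups = {
        key: SweepGroup(
            key[0],
            key[1],
            e["amp"],
            e["n"],
            np.concatenate(e["idx"]) if e["idx"] else np.empty(0, dtype=np.int64),
            np.concatenate(e["rel"]) if e["rel"] else np.empty(0),
            t_max,
        )
        for key, e in acc.items()
    }
    return TriggeredSweeps(groups, t_max)


def build_psth(group: SweepGroup, bin_ms: float = 0.5) -> pd.DataFrame:
    """PSTH of firing rate (Hz) vs time relative to PSC onset.

    Counts are normalized per sweep and per bin width:
    ``rate = count / (n_sweeps * bin)``.
    """
    if bin_ms <= 0:
        raise ValueError(f"bin must be > 0, got {bin_ms}")
    edges = np.arange(-group.t_max, group.t_max + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(group.rel_times_ms, bins=edges)
    rate = counts / (group.n_sweeps * bin_ms * 1e-3)
    return pd.DataFrame(
        {
            "time_ms": (edges[:-1] + edges[1:]) / 2.0,
            "count": counts,
            "rate_hz": rate,
        }
    )


def window_probs(group: SweepGroup, T: float) -> WindowProbs:
    """Estimate P_pre and P_post at window length T (ms)."""
    if group.n_sweeps == 0:
        raise ValueError("cannot estimate window probabilities from zero sweeps")
    pre, post = group.window_counts(T)
    return WindowProbs(
        T=T,
        p_pre=float((pre > 0).mean()),
        p_post=float((post > 0).mean()),
        n_sweeps=group.n_sweeps,
        mean_count_pre=float(pre.mean()),
        mean_count_post=float(post.mean()),
    )


def _binom_quantile(p_target: float, n: int, p: float) -> int:
    """Smallest k with Binom(n, p) CDF >= p_target (binoinv convention)."""
    return int(stats.binom.ppf(p_target, n, p))


def parametric_detection(
    p_pre: float,
    p_post: float,
    n: int,
    alpha: float = 0.05,
    sign: Sign = "excitatory",
) -> float:
    """Parametric (binomial) detection probability for a population of N sweeps.

    Excitatory: ``P[B(N, P_post) > q]`` with ``q`` the (1 - alpha) quantile of
    ``B(N, P_pre)``; inhibitory: ``P[B(N, P_post) < q']`` with ``q'`` the
    alpha quantile.  Both comparisons are strict, so with ``P_post = P_pre``
    the result is at most alpha by the quantile definition.
    """
    if not (0 <= p_pre <= 1 and 0 <= p_post <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n < 1:
        raise ValueError("population size must be >= 1")
    if sign == "excitatory":
        q = _binom_quantile(1.0 - alpha, n, p_pre)
        return float(stats.binom.sf(q, n, p_post))
    q = _binom_quantile(alpha, n, p_pre)
    return float(stats.binom.cdf(q - 1, n, p_post))


def bootstrap_detection(
    group: SweepGroup,
    T: float,
    n: int,
    n_sets: int = 100,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    replace: bool = True,
) -> tuple[float, float]:
    """Bootstrap detection probability; returns (mean, SD) over repetitions.

    Per repetition: draw ``n_sets`` trial sets of ``n`` sweeps; the
    pre-signal distribution is the collection of set-level pre-window count
    sums over all trial sets, whose empirical (1 - alpha) / alpha quantile is
    the decoder threshold; the fraction of trial sets whose post-window count
    sum falls strictly above (excitatory) / below (inhibitory) the threshold
    estimates detection.  Resampling is with replacement by default.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pre, post = group.window_counts(T)
    if not replace and group.n_sweeps < n:
        raise ValueError(f"{group.n_sweeps} sweeps cannot supply sets of {n} without replacement")
    estimates = np.empty(n_reps)
    for rep in range(n_reps):
        if replace:
            idx = rng.integers(0, group.n_sweeps, size=(n_sets, n))
            pre_sums = pre[idx].sum(axis=1)
            post_sums = post[idx].sum(axis=1)
        else:
            pre_sums = np.empty(n_sets, dtype=np.int64)
            post_sums = np.empty(n_sets, dtype=np.int64)
            for s in range(n_sets):
                idx = rng.choice(group.n_sweeps, size=n, replace=False)
                pre_sums[s] = pre[idx].sum()
                post_sums[s] = post[idx].sum()
        if group.sign == "excitatory":
            q = np.quantile(pre_sums, 1.0 - alpha, method="inverted_cdf")
            estimates[rep] = (post_sums > q).mean()
        else:
            q = np.quantile(pre_sums, alpha, method="inverted_cdf")
            estimates[rep] = (post_sums < q).mean()
    return float(estimates.mean()), float(estimates.std())


def detection_surface(
    sweeps: TriggeredSweeps,
    t_grid: Sequence[float] = tuple(np.round(np.arange(0.4, 15.0 + 1e-9, 0.4), 10)),
    n_list: Sequence[int] = (250, 500, 1000, 2000),
    method: Literal["parametric", "bootstrap"] = "parametric",
    alpha: float = 0.05,
    sd_pA: float | None = None,
    rate_hz: float | None = None,
    n_sets: int = 100,
    n_reps: int = 100,
    seed: int = 0,
    keys: Sequence[tuple[Sign, int]] | None = None,
) -> pd.DataFrame:
    """Detection probability over (sign, amplitude class, T, N) as tidy rows.

    ``sd_pA`` (the injected-current SD) adds an ``amplitude_sd_units``
    column; ``rate_hz`` is carried through for multi-rate comparisons.
    Bootstrap rows carry the repetition SD in ``dispersion``.
    """
    if len(t_grid) == 0 or len(n_list) == 0:
        raise ValueError("T grid and N list must be nonempty")
    rows = []
    for key in keys if keys is not None else sweeps.keys():
        group = sweeps.groups[key]
        if group.n_sweeps == 0:
            continue
        for i_t, T in enumerate(t_grid):
            wp = window_probs(group, T)
            for n in n_list:
                if method == "parametric":
                    det, disp = parametric_detection(wp.p_pre, wp.p_post, n, alpha, group.sign), np.nan
                else:
                    det, disp = bootstrap_detection(
                        group,
                        T,
                        n,
                        n_sets,
                        n_reps,
                        alpha,
                        np.random.default_rng(
                            np.random.SeedSequence([seed, key[1], i_t, n, 0 if key[0] == "excitatory" else 1])
                        ),
                    )
                rows.append(
                    {
                        "sign": group.sign,
                        "amplitude_class": group.amplitude_class,
                        "amplitude_pA": group.amplitude_pA,
                        "amplitude_sd_units": group.amplitude_pA / sd_pA if sd_pA else np.nan,
                        "T_ms": T,
                        "N": n,
                        "rate_Hz": rate_hz if rate_hz is not None else np.nan,
                        "method": method,
                        "detection_prob": det,
                        "dispersion": disp,
                        "n_sweeps": group.n_sweeps,
                        "p_pre": wp.p_pre,
                        "p_post": wp.p_post,
                    }
                )
    return pd.DataFrame(rows)


def shift_triggers(triggers: pd.DataFrame, offset_s: float, duration: float) -> pd.DataFrame:
    """Circularly shift onset times by ``offset_s`` modulo the episode duration.

    Destroys the trigger/spike alignment while preserving both marginal
    statistics — the null control for decoder calibration.
    """
    out = triggers.copy()
    out["onset_time_s"] = np.mod(out["onset_time_s"].to_numpy() + offset_s, duration)
    return out.sort_values("onset_time_s", ignore_index=True)
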