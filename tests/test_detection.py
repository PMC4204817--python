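"""Decoder: sweep collection, PSTH, window probabilities, detection formulas."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pscmix as pm
from pscmix.detection import SweepGroup
from pscmix.neuron import Episode, EpisodeSet


def toy_episode_set(spikes_s, onsets_s, duration=20.0, discard=2.0, sign="excitatory", cls=0):
    trig = pd.DataFrame(
        {
            "neuron_id": 0,
            "sign": sign,
            "amplitude_pA": 50.0,
            "amplitude_class": cls,
            "onset_time_s": np.asarray(onsets_s, dtype=float),
        }
    )
    ep = Episode(0, np.asarray(spikes_s, dtype=float), trig, 0.0)
    return EpisodeSet([ep], duration, discard, 0.05)


def bernoulli_group(p_pre, p_post, n_sweeps, seed, sign="excitatory") -> SweepGroup:
    """Synthetic sweeps with independent pre/post spike indicators."""
    rng = np.random.default_rng(seed)
    pre = rng.random(n_sweeps) < p_pre
    post = rng.random(n_sweeps) < p_post
    idx = np.concatenate([np.nonzero(pre)[0], np.nonzero(post)[0]])
    rel = np.concatenate([np.full(pre.sum(), -2.5), np.full(post.sum(), 2.5)])
    return SweepGroup(sign, 0, 50.0, n_sweeps, idx, rel, t_max=15.0)


class TestCollectSweeps:
    def test_single_trigger_relative_time(self):
        eps = toy_episode_set([10.003], [10.0])
        sweeps = pm.collect_sweeps(eps, 15.0)
        g = sweeps.group("excitatory", 0)
        assert g.n_sweeps == 1
        assert np.allclose(g.rel_times_ms, [3.0])

    def test_trigger_in_discard_window_excluded(self):
        eps = toy_episode_set([1.001, 10.003], [1.0, 10.0])
        g = pm.collect_sweeps(eps, 15.0).group("excitatory", 0)
        assert g.n_sweeps == 1  # only the 10 s trigger survives

    def test_trigger_near_episode_edge_excluded(self):
        eps = toy_episode_set([19.999], [19.995], duration=20.0)
        g = pm.collect_sweeps(eps, 15.0).group("excitatory", 0)
        assert g.n_sweeps == 0

    def test_sweep_counts_match_trigger_counts(self, model_runs, sweeps_5hz):
        # direct count oracle: eligible triggers per (sign, class)
        run = model_runs[5.0]
        t_max_s = 15.0 / 1000.0
        expected: dict = {}
        for ep in run.episodes:
            t = ep.triggers
            ok = (t.onset_time_s >= run.discard) & (t.onset_time_s <= run.duration - t_max_s)
            for (sign, cls), sub in t[ok].groupby(["sign", "amplitude_class"]):
                expected[(sign, cls)] = expected.get((sign, cls), 0) + len(sub)
        for key, n_exp in expected.items():
            assert sweeps_5hz.groups[(key[0], int(key[1]))].n_sweeps == n_exp


class TestPSTH:
    def test_uniform_spikes_give_flat_histogram(self):
        rng = np.random.default_rng(0)
        duration, rate = 500.0, 20.0
        spikes = np.sort(rng.uniform(2.0, duration, int(rate * duration)))
        onsets = np.sort(rng.uniform(3.0, duration - 1.0, 6000))
        eps = toy_episode_set(spikes, onsets, duration=duration)
        psth = pm.build_psth(pm.collect_sweeps(eps, 15.0).group("excitatory", 0), bin_ms=5.0)
        assert psth.rate_hz.mean() == pytest.approx(rate, rel=0.05)
        assert psth.rate_hz.std() < 0.25 * rate

    def test_histogram_total_equals_spike_count_in_window(self, sweeps_5hz):
        g = sweeps_5hz.pooled("excitatory")
        psth = pm.build_psth(g, bin_ms=0.5)
        assert psth["count"].sum() == g.rel_times_ms.size

    def test_post_onset_rate_elevation_for_large_excitatory_classes(self, sweeps_5hz):
        """Strong excitatory inputs raise the population rate after onset,
        with a similar time course across amplitude classes."""
        peaks = []
        top = [k for k in sweeps_5hz.keys() if k[0] == "excitatory"][-3:]
        for key in top:
            psth = pm.build_psth(sweeps_5hz.groups[key], bin_ms=1.0)
            pre = psth[psth.time_ms < 0].rate_hz.mean()
            post = psth[(psth.time_ms > 0) & (psth.time_ms < 8)]
            assert post.rate_hz.max() > 1.5 * pre
            peaks.append(post.rate_hz.idxmax())
        times = psth.time_ms[peaks].to_numpy()
        assert times.max() - times.min() <= 4.0  # similar latency-to-peak

    def test_invalid_bin_rejected(self, sweeps_5hz):
        with pytest.raises(ValueError):
            pm.build_psth(sweeps_5hz.pooled("excitatory"), bin_ms=0.0)


class TestWindowProbs:
    def test_no_spikes_gives_zero(self):
        g = SweepGroup("excitatory", 0, 50.0, 10, np.empty(0, int), np.empty(0), 15.0)
        wp = pm.window_probs(g, 5.0)
        assert wp.p_pre == 0.0 and wp.p_post == 0.0

    def test_all_sweeps_occupied_gives_one(self):
        idx = np.repeat(np.arange(10), 2)
        rel = np.tile([-1.0, 1.0], 10)
        g = SweepGroup("excitatory", 0, 50.0, 10, idx, rel, 15.0)
        wp = pm.window_probs(g, 5.0)
        assert wp.p_pre == 1.0 and wp.p_post == 1.0

    def test_manual_enumeration_oracle(self):
        # 10 sweeps: spikes in the pre window for sweeps 0,1; post for 0,4,7;
        # sweep 9 has a spike outside the 5 ms windows
        idx = np.array([0, 1, 0, 4, 7, 9])
        rel = np.array([-2.0, -4.9, 0.5, 3.0, 4.99, 12.0])
        g = SweepGroup("excitatory", 0, 50.0, 10, idx, rel, 15.0)
        wp = pm.window_probs(g, 5.0)
        assert wp.p_pre == pytest.approx(0.2)
        assert wp.p_post == pytest.approx(0.3)
        assert wp.n_sweeps == 10

    def test_indicator_and_count_estimates_agree_at_short_windows(self, sweeps_5hz):
        # short windows at a few Hz: at most one spike per sweep
        for sign in ("excitatory", "inhibitory"):
            wp = pm.window_probs(sweeps_5hz.pooled(sign), 5.0)
            assert wp.mean_count_pre == pytest.approx(wp.p_pre, abs=2e-3)
            assert wp.mean_count_post == pytest.approx(wp.p_post, abs=2e-3)

    def test_zero_sweeps_error(self):
        g = SweepGroup("excitatory", 0, 50.0, 0, np.empty(0, int), np.empty(0), 15.0)
        with pytest.raises(ValueError):
            pm.window_probs(g, 5.0)


def brute_force_detection(p_pre, p_post, n, alpha=0.05, sign="excitatory"):
    """Independent oracle: explicit binomial-CDF summation."""
    k = np.arange(n + 1)
    cdf_pre = stats.binom.cdf(k, n, p_pre)
    pmf_post = stats.binom.pmf(k, n, p_post)
    if sign == "excitatory":
        q = k[cdf_pre >= 1 - alpha][0]
        return pmf_post[k > q].sum()
    q = k[cdf_pre >= alpha][0]
    return pmf_post[k < q].sum()


class TestParametricDetection:
    @pytest.mark.parametrize("sign", ["excitatory", "inhibitory"])
    def test_matches_brute_force_oracle(self, sign):
        for n in (250, 500, 1000, 2000):
            for p_pre in (0.001, 0.005, 0.02):
                for p_post in (0.0005, 0.001, 0.003, 0.01, 0.05):
                    got = pm.parametric_detection(p_pre, p_post, n, 0.05, sign)
                    want = brute_force_detection(p_pre, p_post, n, 0.05, sign)
                    assert got == pytest.approx(want, abs=1e-10)

    def test_poisson_limit_cross_check(self):
        # B(1000, 0.001) ~ Poisson(1): q = 3; detection = P[Poisson(3) > 3]
        got = pm.parametric_detection(0.001, 0.003, 1000)
        assert got == pytest.approx(1.0 - stats.poisson.cdf(3, 3.0), abs=5e-3)
        assert got == pytest.approx(0.35, abs=0.01)

    @pytest.mark.parametrize("sign", ["excitatory", "inhibitory"])
    def test_null_calibrated_below_alpha(self, sign):
        for n in (1, 10, 250, 1000, 2000):
            for p in (0.0, 0.001, 0.02, 0.3, 1.0):
                assert pm.parametric_detection(p, p, n, 0.05, sign) <= 0.05 + 1e-12

    def test_certain_detection(self):
        assert pm.parametric_detection(0.0, 1.0, 100) == pytest.approx(1.0)

    def test_monotone_in_n_when_post_exceeds_pre(self):
        dets = [pm.parametric_detection(0.005, 0.012, n) for n in (250, 500, 1000, 2000)]
        assert np.all(np.diff(dets) > 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pm.parametric_detection(1.5, 0.5, 100)
        with pytest.raises(ValueError):
            pm.parametric_detection(0.1, 0.2, 0)


class TestBootstrapDetection:
    def test_null_case_at_most_alpha(self):
        g = bernoulli_group(0.02, 0.02, 50000, seed=1)
        det, sd = pm.bootstrap_detection(g, 5.0, 1000, n_sets=50, n_reps=20, seed=2)
        assert det <= 0.05 + 3 * max(sd / np.sqrt(20), 0.01)

    @pytest.mark.parametrize(
        "p_pre,p_post,sign",
        [(0.005, 0.015, "excitatory"), (0.02, 0.008, "inhibitory")],
    )
    def test_agrees_with_parametric_formula(self, p_pre, p_post, sign):
        g = bernoulli_group(p_pre, p_post, 100000, seed=3, sign=sign)
        wp = pm.window_probs(g, 5.0)
        want = pm.parametric_detection(wp.p_pre, wp.p_post, 1000, 0.05, sign)
        got, _ = pm.bootstrap_detection(g, 5.0, 1000, n_sets=100, n_reps=50, seed=4)
        assert got == pytest.approx(want, abs=0.05)

    def test_same_seed_reproducible(self):
        g = bernoulli_group(0.01, 0.03, 20000, seed=5)
        a = pm.bootstrap_detection(g, 5.0, 500, 20, 10, seed=6)
        b = pm.bootstrap_detection(g, 5.0, 500, 20, 10, seed=6)
        assert a == b

    def test_without_replacement_needs_enough_sweeps(self):
        g = bernoulli_group(0.01, 0.03, 100, seed=7)
        with pytest.raises(ValueError):
            pm.bootstrap_detection(g, 5.0, 500, 10, 5, seed=8, replace=False)


class TestDetectionSurface:
    def test_values_in_unit_interval_and_grid_complete(self, sweeps_5hz):
        surf = pm.detection_surface(
            sweeps_5hz, t_grid=(3.0, 5.0), n_list=(250, 1000), sd_pA=100.0
        )
        assert ((surf.detection_prob >= 0) & (surf.detection_prob <= 1)).all()
        occupied = [k for k in sweeps_5hz.keys() if sweeps_5hz.groups[k].n_sweeps > 0]
        assert len(surf) == 2 * 2 * len(occupied)
        assert np.allclose(surf.amplitude_sd_units, surf.amplitude_pA / 100.0)

    def test_parametric_monotone_in_T_when_probability_gap_grows(self):
        # synthetic window probabilities with a growing post/pre gap
        dets = [
            pm.parametric_detection(0.002 * T, 0.002 * T + 0.004 * T, 1000)
            for T in (1.0, 2.0, 4.0, 8.0)
        ]
        assert np.all(np.diff(dets) >= 0)

    def test_larger_population_detects_earlier(self, sweeps_5hz):
        """Latency to half-maximum detection shrinks as N grows."""
        g = sweeps_5hz.pooled("excitatory", classes=range(24, 32))
        t_grid = (1.0, 2.0, 3.0, 5.0, 7.0, 10.0)
        latency = {}
        for n in (250, 2000):
            dets = [
                pm.parametric_detection(*_probs(g, T), n) for T in t_grid
            ]
            above = [t for t, d in zip(t_grid, dets) if d >= 0.5]
            latency[n] = above[0] if above else np.inf
        assert latency[2000] <= latency[250]

    def test_empty_grid_rejected(self, sweeps_5hz):
        with pytest.raises(ValueError):
            pm.detection_surface(sweeps_5hz, t_grid=(), n_list=(250,))


def _probs(group, T):
    wp = pm.window_probs(group, T)
    return wp.p_pre, wp.p_post


class TestShiftTriggers:
    def test_shift_preserves_counts_and_range(self, model_runs):
        run = model_runs[5.0]
        trig = run.episodes[0].triggers
        shifted = pm.shift_triggers(trig, 11.3, run.duration)
        assert len(shifted) == len(trig)
        assert shifted.onset_time_s.between(0, run.duration).all()
        assert sorted(shifted.neuron_id.unique()) == sorted(trig.neuron_id.unique())
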