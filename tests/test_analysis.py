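"""Burst/event segmentation, interval statistics, rates and the decoder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstnet import analysis
from burstnet.analysis import (
    SINGLET, BURST_FIRST, BURST_MEMBER, classify_spikes, interval_cv,
    population_rates, burst_fraction, net_current_stats, decode_multiplexed,
)
from burstnet.fixtures_io import FixtureSpec, generate_labeled_trains


def brute_force_segments(times_s, thr_s=0.016):
    """Independent segmentation oracle: split the train wherever the gap is
    >= threshold; every resulting group of >= 2 spikes is one burst."""
    groups, current = [], []
    for t in times_s:
        if current and t - current[-1] >= thr_s:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return groups


class TestClassifySpikes:
    def test_burst_plus_singlet(self):
        lab = classify_spikes(np.array([0.0, 0.010, 0.020, 0.100]))
        assert lab.n_events == 2 and lab.n_bursts == 1
        assert list(lab.labels) == [BURST_FIRST, BURST_MEMBER, BURST_MEMBER, SINGLET]
        assert lab.burst_sizes.tolist() == [3]
        assert lab.burst_times.tolist() == [0.0]

    def test_all_singlets(self):
        lab = classify_spikes(np.array([0.0, 0.050, 0.120]))
        assert lab.n_events == 3 and lab.n_bursts == 0

    def test_empty_train(self):
        lab = classify_spikes(np.empty(0))
        assert lab.n_events == 0 and lab.n_bursts == 0

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            classify_spikes(np.array([0.1, 0.05]))

    def test_threshold_boundary_is_exclusive(self):
        # exactly 16 ms is not a burst
        assert classify_spikes(np.array([0.0, 0.016])).n_bursts == 0
        assert classify_spikes(np.array([0.0, 0.0159])).n_bursts == 1

    def test_calcium_verification_demotes_unconfirmed(self):
        t = np.array([0.0, 0.010, 0.200, 0.208])
        lab = classify_spikes(t, calcium_events=np.array([0.204]))
        # first candidate burst has no calcium event within +-5 ms -> demoted
        assert lab.n_bursts == 1
        assert lab.burst_times.tolist() == [0.200]
        assert lab.n_events == 3

    def test_matches_brute_force_on_random_trains(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = rng.integers(0, 60)
            t = np.sort(rng.uniform(0.0, 1.0, n))
            lab = classify_spikes(t)
            groups = brute_force_segments(t)
            bursts = [g for g in groups if len(g) >= 2]
            assert lab.n_bursts == len(bursts)
            assert lab.n_events == len(groups)
            assert lab.burst_times.tolist() == [g[0] for g in bursts]
            assert sorted(lab.burst_sizes.tolist()) == sorted(len(g) for g in bursts)

    @given(st.lists(st.floats(min_value=0.0, max_value=2.0), max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_segmentation_conserves_spikes(self, raw):
        t = np.sort(np.asarray(raw, dtype=float))
        lab = classify_spikes(t)
        n_singlets = int(np.sum(lab.labels == SINGLET))
        assert n_singlets + int(lab.burst_sizes.sum()) == t.size
        assert lab.n_bursts <= lab.n_events <= t.size

    def test_recovers_injected_bursts(self):
        spec = FixtureSpec(event_rate=8.0, burst_prob=0.3, duration=30.0,
                           n_neurons=5, seed=4)
        for times, truth in generate_labeled_trains(spec):
            lab = classify_spikes(times)
            assert lab.n_bursts == truth.n_bursts
            assert lab.n_events == truth.n_events


class TestIntervalCV:
    def test_constant_intervals(self):
        assert interval_cv([0.010, 0.010, 0.010]) == 0.0

    def test_hand_computed(self):
        # population s.d. of [1,2,3] is sqrt(2/3); mean 2
        assert interval_cv([1.0, 2.0, 3.0]) == pytest.approx(np.sqrt(2.0 / 3.0) / 2.0)

    def test_poisson_limit(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(0.1, 10_000)
        assert interval_cv(x) == pytest.approx(1.0, rel=0.03)

    def test_insufficient_intervals_are_nan(self):
        assert np.isnan(interval_cv([0.1]))
        assert np.isnan(interval_cv([]))

    def test_invariant_under_time_rescaling(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, 0.05, 500)
        assert interval_cv(x) == pytest.approx(interval_cv(10.0 * x), rel=1e-12)


class TestPopulationRates:
    def test_single_spike_bin_rate(self):
        _, rate = population_rates([0.0005], n_neurons=100, duration_s=0.01)
        assert rate[0] == pytest.approx(10.0)  # 1/(100 * 0.001)
        assert np.all(rate[1:] == 0.0)

    def test_empty(self):
        _, rate = population_rates([], n_neurons=10, duration_s=0.1)
        assert np.all(rate == 0.0)

    def test_smoothing_preserves_integral(self):
        rng = np.random.default_rng(3)
        times = rng.uniform(0.2, 0.8, 200)
        _, raw = population_rates(times, 10, 1.0)
        _, smooth = population_rates(times, 10, 1.0, smooth_ms=10.0)
        assert smooth.sum() == pytest.approx(raw.sum(), rel=1e-9)


class TestBurstFraction:
    def test_ratio_and_masking(self):
        er = np.array([8.0, 4.0, 0.0])
        br = np.array([2.0, 4.0, 0.0])
        bf = burst_fraction(er, br)
        assert bf[0] == 0.25 and bf[1] == 1.0
        assert np.isnan(bf[2])


class TestNetCurrentStats:
    def test_constant_current(self):
        mean, sd = net_current_stats(np.full((100, 5), 42.0))
        assert mean == 42.0 and sd == 0.0


class TestDecoder:
    def test_perfect_and_negated(self):
        x = np.sin(np.linspace(0, 10, 500))
        res = decode_multiplexed(x, np.full_like(x, 0.5) + 0.1 * x, x, x)
        assert res.r_soma == pytest.approx(1.0)
        res2 = decode_multiplexed(-x, np.full_like(x, 0.5) - 0.1 * x, x, x)
        assert res2.r_soma == pytest.approx(-1.0)
        assert res2.r_dend == pytest.approx(-1.0)

    def test_affine_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=2000)
        y = 3.0 * x + 7.0 + rng.normal(scale=0.05, size=x.size)
        res = decode_multiplexed(x, np.clip(0.5 + 0.01 * x, 0, 1), y, x)
        resid = res.soma_decoded - y
        assert np.abs(resid.mean()) < 0.01
        assert resid.std() == pytest.approx(0.05, rel=0.1)

    def test_constant_trace_gives_nan(self):
        x = np.ones(100)
        res = decode_multiplexed(x, x, np.random.default_rng(0).normal(size=100), x)
        assert np.isnan(res.r_soma)
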