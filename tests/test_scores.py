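"""Dynamics scores: rate, branching, synchrony, Van Rossum, ISI-CV,
stationarity."""

import numpy as np
import pytest

from spikemotifs.scores import (AnalysisWindow, UndefinedScoreError,
                                firing_rate, branching_windowed,
                                branching_avalanche, synchrony_heuristic,
                                van_rossum_distance, van_rossum_score,
                                isi_cv, stationarity_l2)
from spikemotifs.fixtures import gen_poisson_raster

WIN = AnalysisWindow(0.0, 1000.0)


def _raster(spike_times_per_unit):
    units, times = [], []
    for u, ts in enumerate(spike_times_per_unit):
        units += [u] * len(ts)
        times += list(ts)
    order = np.argsort(times, kind="stable")
    return np.asarray(units)[order], np.asarray(times, dtype=float)[order]


class TestFiringRate:
    def test_uniform_ten_spikes_per_second(self):
        units, times = _raster([np.linspace(1, 999, 10)] * 40)
        assert firing_rate(units, times, WIN, np.arange(40)) == \
            pytest.approx(10.0)

    def test_empty_raster_rate_zero(self):
        u = np.empty(0, dtype=int)
        t = np.empty(0)
        assert firing_rate(u, t, WIN, np.arange(5)) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(UndefinedScoreError):
            AnalysisWindow(10.0, 10.0)


class TestBranchingWindowed:
    def test_steady_activity_scores_one(self):
        # equal counts in every 5-ms bin -> sigma exactly 1
        times = np.repeat(np.arange(2.5, 1000, 5.0), 7)
        units = np.tile(np.arange(7), 200)
        sigma = branching_windowed(units, times, WIN)
        assert sigma == pytest.approx(1.0)

    def test_doubling_activity(self):
        # counts 1,2,4,8,... with a one-bin descendant window: ratio 2 at
        # every step
        counts = [2 ** k for k in range(8)]
        units, times = [], []
        for b, c in enumerate(counts):
            for j in range(c):
                units.append(j)
                times.append(b * 5.0 + 2.5)
        sigma = branching_windowed(np.asarray(units), np.asarray(times),
                                   AnalysisWindow(0.0, 40.0),
                                   descendant_span_bins=1)
        assert sigma == pytest.approx(2.0)

    def test_no_spikes_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            branching_windowed(np.empty(0, dtype=int), np.empty(0), WIN)

    def test_out_of_window_spikes_ignored(self):
        times = np.repeat(np.arange(2.5, 1000, 5.0), 5)
        units = np.tile(np.arange(5), 200)
        w = AnalysisWindow(100.0, 900.0)
        base = branching_windowed(units, times, w)
        extra_u = np.concatenate([units, [0] * 50])
        extra_t = np.concatenate([times, np.full(50, 950.0)])
        assert branching_windowed(extra_u, extra_t, w) == \
            pytest.approx(base)


class TestBranchingAvalanche:
    def test_one_descendant_per_ancestor(self):
        # avalanches of constant size: every ancestor bin reproduces itself
        units, times = [], []
        t = 0.0
        for _ in range(30):
            for b in range(4):          # 4 active bins, 3 spikes each
                for j in range(3):
                    units.append(j)
                    times.append(t + b * 5.0 + 1.0)
            t += 40.0                   # empty gap ends the avalanche
        sigma = branching_avalanche(np.asarray(units), np.asarray(times),
                                    AnalysisWindow(0.0, t), n_max=1000)
        assert sigma == pytest.approx(1.0, abs=1e-9)

    def test_all_avalanches_die_immediately(self):
        # single-bin avalanches -> every ancestor has zero descendants
        units = np.zeros(20, dtype=int)
        times = np.arange(20) * 50.0 + 1.0
        sigma = branching_avalanche(units, times,
                                    AnalysisWindow(0.0, 1000.0), n_max=100)
        assert sigma == 0.0

    def test_enumerated_distribution(self):
        # descendants per ancestor drawn from {0,1,2} at {1/4,1/2,1/4}:
        # sigma = 0*0.25 + 1*0.5 + 2*0.25 = 1, with n_a << n_max
        units, times = [], []
        t = 0.0
        pattern = [0, 1, 2, 1]          # frequencies 1/4, 1/2, 1/4
        for d in pattern * 10:
            units.append(0)
            times.append(t + 1.0)
            for j in range(d):
                units.append(j)
                times.append(t + 6.0)
            t += 40.0
        sigma = branching_avalanche(np.asarray(units), np.asarray(times),
                                    AnalysisWindow(0.0, t), n_max=10**6)
        assert sigma == pytest.approx(1.0, abs=0.05)


class TestSynchronyHeuristic:
    def test_identical_traces_fully_synchronous(self, rng):
        trace = rng.normal(size=500)
        V = np.tile(trace, (50, 1))
        assert synchrony_heuristic(V) == pytest.approx(1.0)

    def test_independent_noise_scales_as_one_over_n(self, rng):
        V = rng.normal(size=(1000, 2000))
        assert synchrony_heuristic(V) == pytest.approx(1 / 1000, rel=0.3)

    def test_half_shared_power_scores_half(self, rng):
        n, t = 400, 20000
        common = rng.normal(size=t)
        V = common + rng.normal(size=(n, t))
        assert synchrony_heuristic(V) == pytest.approx(0.5, abs=0.03)

    def test_shift_and_scale_invariance(self, rng):
        V = rng.normal(size=(20, 300))
        s0 = synchrony_heuristic(V)
        assert synchrony_heuristic(3.7 * V - 55.0) == pytest.approx(s0)

    def test_constant_traces_undefined(self):
        with pytest.raises(UndefinedScoreError):
            synchrony_heuristic(np.full((5, 100), -60.0))


class TestVanRossum:
    def test_identical_trains_distance_zero(self):
        t = np.array([10.0, 50.0, 300.0])
        assert van_rossum_distance(t, t) == pytest.approx(0.0, abs=1e-9)

    def test_single_spike_offset_closed_form(self):
        # D^2 = tau (1 - e^{-dt/tau}) for two single-spike trains
        tau = 10.0
        for delta in [1.0, 5.0, 50.0]:
            d = van_rossum_distance(np.array([100.0]),
                                    np.array([100.0 + delta]), tau)
            assert d == pytest.approx(
                np.sqrt(tau * (1 - np.exp(-delta / tau))), rel=1e-9)

    def test_far_apart_limit_sqrt_tau(self):
        d = van_rossum_distance(np.array([0.0]), np.array([1e6]), 10.0)
        assert d == pytest.approx(np.sqrt(10.0), rel=1e-6)

    def test_metric_axioms_on_random_triples(self, rng):
        trains = [np.sort(rng.uniform(0, 200, size=rng.integers(1, 8)))
                  for _ in range(12)]
        for _ in range(30):
            a, b, c = rng.choice(12, size=3, replace=False)
            dab = van_rossum_distance(trains[a], trains[b])
            dba = van_rossum_distance(trains[b], trains[a])
            dac = van_rossum_distance(trains[a], trains[c])
            dcb = van_rossum_distance(trains[c], trains[b])
            assert dab == pytest.approx(dba, rel=1e-9)
            assert dab <= dac + dcb + 1e-9

    def test_poisson_population_baseline_near_nine(self):
        units, times = gen_poisson_raster(800, 8.0, 1000.0, seed=12)
        score = van_rossum_score(units, times, WIN, np.arange(800),
                                 n_pairs=4000, seed=0)
        assert score == pytest.approx(9.0, abs=1.0)


class TestIsiCv:
    def test_periodic_train_cv_zero(self):
        units, times = _raster([np.arange(0, 1000, 10.0)])
        cvs, mean = isi_cv(units, times)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_poisson_cv_near_one(self, rng):
        isi = rng.exponential(10.0, size=100000)
        times = np.cumsum(isi)
        units = np.zeros(len(times), dtype=int)
        _, mean = isi_cv(units, times)
        assert mean == pytest.approx(1.0, abs=0.02)

    def test_sparse_units_excluded(self):
        units, times = _raster([[10.0, 20.0], np.arange(0, 100, 10.0)])
        cvs, _ = isi_cv(units, times)
        assert 0 not in cvs and 1 in cvs


class TestStationarity:
    def test_stationary_signal_small_error(self, rng):
        units, times = gen_poisson_raster(200, 20.0, 2000.0, seed=5)
        err = stationarity_l2(units, times, AnalysisWindow(0, 2000.0))
        assert err < 0.5

    def test_ramp_inflates_error(self, rng):
        # strongly trending rate vs its stationary control
        t_trend = np.sort(2000.0 * np.sqrt(rng.uniform(size=4000)))
        t_flat = np.sort(rng.uniform(0, 2000.0, size=4000))
        u = np.zeros(4000, dtype=int)
        w = AnalysisWindow(0, 2000.0)
        assert stationarity_l2(u, t_trend, w) > \
            2 * stationarity_l2(u, t_flat, w)

    def test_zero_variance_undefined(self):
        units = np.zeros(100, dtype=int)
        times = np.arange(100) * 10.0 + 5.0   # exactly 1 spike per bin
        with pytest.raises(UndefinedScoreError):
            stationarity_l2(units, times, AnalysisWindow(0, 1000.0))
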