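"""Single-neuron and small-circuit behaviour of the AdEx integrator."""

import numpy as np
import pytest
import scipy.sparse as sp

from spikemotifs.adex import (NeuronParams, StimulusConfig, PoissonInput,
                              init_voltages, make_poisson_input,
                              simulate_run, classify_outcome, SimulationRun)
from spikemotifs.netbuild import SynapticNetwork


def _net(W):
    W = sp.csr_matrix(np.asarray(W, dtype=float))
    return SynapticNetwork(weights=W, n_excitatory=W.shape[0],
                           n_inhibitory=0)


PARAMS = NeuronParams()


class TestInitVoltages:
    def test_range(self):
        v = init_voltages(10000, seed=1)
        assert v.min() >= -60.0 and v.max() <= -50.0

    def test_single_unit(self):
        v = init_voltages(1, seed=0)
        assert v.shape == (1,) and -60 <= v[0] <= -50

    def test_uniform_mean(self):
        v = init_voltages(10**6, seed=2)
        assert v.mean() == pytest.approx(-55.0, abs=0.01)


class TestPoissonInput:
    def test_expected_total_spikes(self):
        cfg = StimulusConfig(n_input_units=500, rate_hz=20.0,
                             duration_ms=30.0, seed=4)
        stim = make_poisson_input(cfg, np.arange(500))
        # 0.02 spikes/ms * 30 ms = 0.6 per train, ~300 total
        assert stim.total_spikes == pytest.approx(300, rel=0.25)

    def test_zero_rate_empty(self):
        cfg = StimulusConfig(rate_hz=0.0, seed=1)
        stim = make_poisson_input(cfg, np.arange(500))
        assert stim.total_spikes == 0

    def test_deterministic_for_fixed_seed(self):
        cfg = StimulusConfig(seed=7)
        a = make_poisson_input(cfg, np.arange(500))
        b = make_poisson_input(cfg, np.arange(500))
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta, tb)


class TestSingleNeuron:
    def test_rest_is_fixed_point(self):
        run = simulate_run(_net(np.zeros((1, 1))), PARAMS, None,
                           np.array([PARAMS.E_l]), max_duration_ms=200.0)
        assert len(run.times) == 0
        assert run.outcome == "truncated"

    def test_subthreshold_relaxation_toward_rest(self):
        # V < V_T relaxes to E_l without input (monotone until the slow
        # adaptation current produces its tiny sub-mV rebound)
        run = simulate_run(_net(np.zeros((1, 1))), PARAMS, None,
                           np.array([-55.0]), max_duration_ms=150.0,
                           record_voltages=True, voltage_sample_every=1)
        v = run.seeds["voltage_traces"][0]
        above = v > PARAMS.E_l + 1.0
        assert (np.diff(v)[above[:-1]] < 0).all()
        assert v[-1] == pytest.approx(PARAMS.E_l, abs=0.5)
        assert len(run.times) == 0

    def test_reset_rule_and_adaptation_jump(self):
        # constant suprathreshold drive: after each spike V == E_l at the
        # next sample and each spike adds exactly b to w
        params = NeuronParams(t_ref=0.0)
        stim = make_poisson_input(
            StimulusConfig(n_input_units=1, rate_hz=2000.0,
                           duration_ms=500.0, input_weight_ns=30.0, seed=2),
            np.array([0]))
        run = simulate_run(_net(np.zeros((1, 1))), params, stim,
                           np.array([-55.0]), max_duration_ms=500.0,
                           record_voltages=True, voltage_sample_every=1)
        assert len(run.times) >= 3
        v = run.seeds["voltage_traces"][0]
        steps = np.rint(run.times / 0.1).astype(int) - 1
        for s in steps[:-1]:
            assert v[s] == pytest.approx(params.E_l)

    def test_conductance_exponential_decay(self):
        # an isolated synaptic increment decays as exp(-t/tau_e): probe via
        # a two-neuron chain where neuron 0 spikes once
        W = np.zeros((2, 2))
        W[0, 1] = 5.0
        stim = make_poisson_input(
            StimulusConfig(n_input_units=1, rate_hz=500.0, duration_ms=10.0,
                           input_weight_ns=500.0, seed=3), np.array([0]))
        run = simulate_run(_net(W), NeuronParams(), stim,
                           np.array([-55.0, -59.0]), max_duration_ms=100.0)
        assert (run.units == 0).sum() >= 1


class TestNetworkMechanics:
    def test_downstream_conductance_increment_timing(self):
        # strong synapse: presynaptic spike triggers postsynaptic spike
        # within a few ms
        W = np.zeros((2, 2))
        W[0, 1] = 200.0
        stim = make_poisson_input(
            StimulusConfig(n_input_units=1, rate_hz=200.0, duration_ms=10.0,
                           input_weight_ns=300.0, seed=5), np.array([0]))
        run = simulate_run(_net(W), NeuronParams(), stim,
                           np.array([-55.0, -58.0]), max_duration_ms=200.0)
        t0 = run.times[run.units == 0]
        t1 = run.times[run.units == 1]
        assert len(t0) and len(t1)
        assert t1[0] > t0[0]
        assert t1[0] - t0[0] < 5.0

    def test_determinism_byte_for_byte(self):
        rng = np.random.default_rng(0)
        W = sp.csr_matrix((rng.random((20, 20)) < 0.3) * 2.0)
        net = SynapticNetwork(weights=W, n_excitatory=16, n_inhibitory=4)
        stim = make_poisson_input(StimulusConfig(n_input_units=5, seed=9),
                                  np.arange(5))
        v0 = init_voltages(20, seed=3)
        a = simulate_run(net, PARAMS, stim, v0, max_duration_ms=300.0)
        b = simulate_run(net, PARAMS, stim, v0, max_duration_ms=300.0)
        assert np.array_equal(a.units, b.units)
        assert np.array_equal(a.times, b.times)

    def test_dt_refinement_convergence(self):
        # halving dt changes each unit's early spike times of a 10-neuron
        # circuit by < 0.2 ms
        rng = np.random.default_rng(4)
        W = sp.csr_matrix(np.where(rng.random((10, 10)) < 0.4, 60.0, 0.0))
        net = SynapticNetwork(weights=W, n_excitatory=10, n_inhibitory=0)
        params = NeuronParams(t_ref=5.0)
        stim = make_poisson_input(
            StimulusConfig(n_input_units=3, rate_hz=100.0, duration_ms=20.0,
                           input_weight_ns=150.0, seed=6), np.arange(3))
        v0 = init_voltages(10, seed=8)
        runs = {dt: simulate_run(net, params, stim, v0,
                                 max_duration_ms=100.0, dt=dt)
                for dt in (0.1, 0.05)}
        a, b = runs[0.1], runs[0.05]
        checked = 0
        for u in range(10):
            ta = a.times[a.units == u][:3]
            tb = b.times[b.units == u][:3]
            n = min(len(ta), len(tb))
            if n:
                assert np.abs(ta[:n] - tb[:n]).max() < 0.2
                checked += 1
        assert checked >= 5


class TestOutcomeClassification:
    def _run(self, last_spike, max_ms=1000.0):
        return SimulationRun(units=np.array([0]),
                             times=np.array([last_spike]),
                             n_units=1, n_excitatory=1,
                             max_duration_ms=max_ms, outcome="?",
                             truncation_time_ms=0.0)

    def test_early_last_spike_truncated(self):
        assert classify_outcome(self._run(700.0)) == "truncated"

    def test_late_spiking_sustained(self):
        assert classify_outcome(self._run(995.0)) == "sustained"

    def test_empty_raster_truncated_at_zero(self):
        run = SimulationRun(units=np.empty(0, dtype=int),
                            times=np.empty(0), n_units=1, n_excitatory=1,
                            max_duration_ms=1000.0, outcome="?",
                            truncation_time_ms=0.0)
        assert classify_outcome(run) == "truncated"
        assert run.last_spike_time() == 0.0
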