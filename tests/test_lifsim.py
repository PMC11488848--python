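import numpy as np
import pytest

from clusterplay._rng import substream
from clusterplay.config import RunConfig, with_overrides
from clusterplay.lifsim import (
    NeuronState,
    StimulusProtocol,
    initialize_state,
    location_cue_rates,
    simulate_run_trials,
    simulate_session,
    simulate_sleep,
)
from clusterplay.netgen import build_network


@pytest.fixture(scope="module")
def small_net():
    """Tiny quiet network for single-neuron dynamics tests."""
    cfg = with_overrides(
        RunConfig(),
        network={"n": 8, "excit_fraction": 0.75, "n_clusters": 2,
                 "cluster_participation": 1.0, "p_ee": 0.2},
        inputs={"rate_peak": 0.0},
    )
    return build_network(cfg, seed=0)


def _silent_state(n):
    z = np.zeros(n)
    return NeuronState(v=np.full(n, -70e-3), g_e=z.copy(), g_i=z.copy(),
                       g_sra=z.copy(), g_ext=z.copy())


class TestLocationCues:
    def test_track_ends_and_midpoint(self):
        assert location_cue_rates(0.0) == (5000.0, 0.0)
        assert location_cue_rates(1.0) == (0.0, 5000.0)
        left, right = location_cue_rates(0.5)
        assert left == right == 2500.0

    def test_rates_sum_to_peak_everywhere(self):
        for x in np.linspace(0, 1, 11):
            assert sum(location_cue_rates(x)) == pytest.approx(5000.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            location_cue_rates(1.5)


class TestInitialState:
    def test_steady_state_mean_external_conductance(self):
        # Win * rG * tauE = 72 pS * 5000 Hz * 10 ms = 3.6 nS per input
        net = build_network(RunConfig(), seed=2)
        w = net.input_weights("sleep")
        st = initialize_state(net, w, StimulusProtocol.sleep(1.0), substream(0, "i"))
        assert st.g_ext[:375].mean() == pytest.approx(3.6e-9, rel=0.05)
        assert np.all(st.g_ext >= 0)

    def test_recurrent_and_sra_conductances_start_at_zero(self):
        net = build_network(RunConfig(), seed=2)
        w = net.input_weights(0)
        st = initialize_state(net, w, StimulusProtocol.run_lap("right"), substream(0, "i"))
        assert not st.g_e.any() and not st.g_i.any() and not st.g_sra.any()
        assert np.all(st.v == -70e-3)

    def test_zero_rate_gives_zero_conductance(self):
        cfg = with_overrides(RunConfig(), inputs={"rate_peak": 0.0})
        net = build_network(cfg, seed=2)
        st = initialize_state(
            net, net.input_weights("sleep"), StimulusProtocol.sleep(1.0), substream(0, "i")
        )
        assert not st.g_ext.any()


class TestMembraneDynamics:
    def test_leak_fixed_point(self, small_net):
        rec = simulate_session(
            small_net,
            small_net.input_weights("sleep"),
            StimulusProtocol.sleep(0.2),
            substream(0, "s"),
            state=_silent_state(8),
            record_v=0,
        )
        assert rec.n_spikes == 0
        assert np.allclose(rec.meta["v_trace"], -70e-3, atol=1e-12)

    def test_exponential_relaxation_with_tau_m(self, small_net):
        # V(40 ms) - EL = (V0 - EL)/e for tau_m = 40 ms
        state = _silent_state(8)
        state.v[:] = -60e-3
        rec = simulate_session(
            small_net,
            small_net.input_weights("sleep"),
            StimulusProtocol.sleep(0.2),
            substream(0, "s"),
            state=state,
            record_v=0,
        )
        v = rec.meta["v_trace"]
        idx = int(40e-3 / 1e-4) - 1
        expected = -70e-3 + 10e-3 / np.e
        assert v[idx] == pytest.approx(expected, abs=2e-5)

    def test_clamped_drive_steady_state(self):
        # with constant g_ext = g0 and no spiking, V -> gL*EL / (gL + g0)
        cfg = with_overrides(
            RunConfig(),
            network={"n": 8, "excit_fraction": 0.75, "n_clusters": 2,
                     "cluster_participation": 1.0, "p_ee": 0.2},
            inputs={"rate_peak": 0.0},
            cells={"v_thresh": 0.0, "tau_e": 1e6, "tau_m": 40e-3},
        )
        net = build_network(cfg, seed=0)
        state = _silent_state(8)
        g0 = 5e-9
        state.g_ext[:] = g0  # tau_e huge -> effectively clamped
        rec = simulate_session(
            net, net.input_weights("sleep"), StimulusProtocol.sleep(1.0),
            substream(0, "s"), state=state, record_v=0,
        )
        expected = 10e-9 * -70e-3 / (10e-9 + g0)
        assert rec.meta["v_trace"][-1] == pytest.approx(expected, rel=1e-3)

    def test_presynaptic_spike_steps_conductance_and_spike_recorded(self, small_net):
        # drive neuron 0 over threshold; its targets' g_E must rise
        state = _silent_state(8)
        state.v[0] = -50.1e-3
        state.g_ext[0] = 20e-9
        rec = simulate_session(
            small_net, small_net.input_weights("sleep"),
            StimulusProtocol.sleep(0.05), substream(0, "s"), state=state,
        )
        assert 0 in rec.ids
        t0 = rec.spikes_of(0)[0]
        assert 0 < t0 <= 0.05
        targets = np.flatnonzero(small_net.conn.ee[0])
        if len(targets):
            g_e = rec.meta["final_state"].g_e
            assert g_e[targets].max() > 0


class TestPoissonInput:
    def test_lone_input_spike_count_matches_rate(self):
        # one neuron, context input only: increments over 100 s ~ Poisson(rate*T)
        cfg = with_overrides(
            RunConfig(),
            network={"n": 8, "excit_fraction": 0.75, "n_clusters": 2,
                     "cluster_participation": 1.0, "p_ee": 0.2},
            inputs={"rate_peak": 500.0, "w_in_mean": 1e-12, "w_in_sd": 0.0,
                    "w_context_sd": 0.0},
            cells={"v_thresh": 1.0},  # never spikes
        )
        net = build_network(cfg, seed=0)
        w = net.input_weights("sleep")
        state = _silent_state(8)
        rec = simulate_session(
            net, w, StimulusProtocol.sleep(100.0), substream(3, "s"), state=state
        )
        g = rec.meta["final_state"].g_ext
        # mean conductance ~ w * rate * tau_e; loose Poisson-error bound
        assert g[:6].mean() == pytest.approx(1e-12 * 500 * 0.01, rel=0.15)

    def test_conductances_stay_nonnegative(self, fiducial_network):
        rec = simulate_sleep(fiducial_network, duration=2.0)
        fs = rec.meta["final_state"]
        for g in (fs.g_e, fs.g_i, fs.g_sra, fs.g_ext):
            assert np.all(g >= 0)


class TestSessions:
    def test_spike_record_invariants(self, fiducial_network):
        rec = simulate_sleep(fiducial_network, duration=5.0)
        assert np.all(np.diff(rec.times) >= 0)
        assert rec.times[0] > 0 and rec.times[-1] <= 5.0 + 1e-9
        assert rec.ids.max() < 500

    def test_run_session_rates_plausible(self, fiducial_network):
        laps = simulate_run_trials(fiducial_network, 0, "left", n_laps=2)
        r = np.mean([l.rates()[:375] for l in laps])
        assert 0.1 < r < 20.0

    def test_determinism(self, fiducial_network):
        a = simulate_sleep(fiducial_network, duration=3.0)
        b = simulate_sleep(fiducial_network, duration=3.0)
        assert np.array_equal(a.ids, b.ids)
        assert np.array_equal(a.times, b.times)

    def test_zero_duration_sleep_is_empty(self, fiducial_network):
        rec = simulate_sleep(fiducial_network, duration=0.0)
        assert rec.n_spikes == 0

    def test_buffer_overflow_raises(self, fiducial_network):
        with pytest.raises(RuntimeError, match="runaway"):
            simulate_session(
                fiducial_network,
                fiducial_network.input_weights("sleep"),
                StimulusProtocol.sleep(2.0),
                substream(0, "s"),
                mean_rate_capacity=0.01,
            )


class TestIntegrationConvergence:
    def test_run_session_rates_converge_in_dt(self):
        rates = {}
        for dt in (1e-4, 5e-5):
            cfg = with_overrides(RunConfig(), cells={"dt": dt})
            net = build_network(cfg, seed=1)
            laps = simulate_run_trials(net, 0, "left", n_laps=3)
            rates[dt] = np.mean([l.rates()[:375] for l in laps])
        assert abs(rates[1e-4] - rates[5e-5]) / rates[5e-5] < 0.05

    def test_sleep_session_rates_converge_in_dt(self):
        # fluctuation-driven regime: looser bound dominated by the
        # stochastic realization difference between the two streams
        rates = {}
        for dt in (1e-4, 5e-5):
            cfg = with_overrides(RunConfig(), cells={"dt": dt})
            net = build_network(cfg, seed=1)
            rates[dt] = simulate_sleep(net, duration=60.0).rates()[:375].mean()
        assert abs(rates[1e-4] - rates[5e-5]) / rates[5e-5] < 0.25
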