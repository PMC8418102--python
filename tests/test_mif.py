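"""Full-model (MIF) simulator: kick primitives, event rates, projection,
determinism, and conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammarkov import make_regime
from gammarkov.containers import POP_E, POP_I
from gammarkov.mif import (
    R,
    MIFNetworkState,
    apply_e_kick,
    apply_external_kick,
    apply_i_kick,
    exit_refractory,
    fire,
    pending_pool_trace,
    project_cg,
    run_mif,
    total_event_rates,
)
from gammarkov.stats import firing_rates, ssi


@pytest.fixture(scope="module")
def params():
    return make_regime("Syn")


class TestKickPrimitives:
    def test_external_kick_increments_one_level(self, params):
        assert apply_external_kick(50, params) == (51, False)

    def test_external_kick_at_one_below_threshold_fires(self, params):
        v, fired = apply_external_kick(99, params)
        assert fired and v is R

    def test_refractory_unaffected_by_any_kick(self, params):
        rng = np.random.default_rng(0)
        assert apply_external_kick(R, params) == (R, False)
        assert apply_e_kick(R, 20, params) == (R, False)
        assert apply_i_kick(R, 20, params, rng) is R

    def test_e_kick_fires_from_the_excitable_strip(self, params):
        v, fired = apply_e_kick(85, params.S_EE, params)
        assert fired  # 85 + 20 >= 100
        assert apply_e_kick(50, params.S_EE, params) == (70, False)

    def test_i_kick_at_reversal_is_a_no_op(self, params):
        rng = np.random.default_rng(0)
        assert apply_i_kick(-66, 20, params, rng) == -66

    def test_i_kick_stochastic_rounding_distribution(self, params):
        # v=34, S=20: ideal decrement 100/166*20 = 12.048..., so the
        # realized decrement is 12 with probability ~0.952, else 13
        rng = np.random.default_rng(1)
        outs = np.array([34 - apply_i_kick(34, 20, params, rng)
                         for _ in range(20000)])
        assert set(np.unique(outs)) == {12, 13}
        assert np.mean(outs == 13) == pytest.approx(0.048, abs=0.006)

    @given(v=st.integers(min_value=-66, max_value=99),
           s=st.integers(min_value=1, max_value=30))
    @settings(deadline=None, derandomize=True)
    def test_i_kick_bounded_below_by_reversal(self, v, s, params):
        rng = np.random.default_rng(abs(hash((v, s))) % 2**31)
        v2 = apply_i_kick(v, s, params, rng)
        assert params.V_I <= v2 <= v


class TestFireAndRefractory:
    def test_full_connectivity_hits_every_pool(self):
        p = make_regime("Syn", P_EE=1.0, P_IE=1.0)
        state = MIFNetworkState.at_rest(p)
        counts = fire(0, state, p, np.random.default_rng(0))
        assert counts == {"E": 75, "I": 25}
        assert (state.h_e == 1).all()

    def test_zero_connectivity_hits_nothing(self):
        p = make_regime("Syn", P_EE=0.0, P_IE=0.0)
        state = MIFNetworkState.at_rest(p)
        fire(0, state, p, np.random.default_rng(0))
        assert state.h_e.sum() == 0

    def test_mean_delivered_kicks_matches_recipient_count(self, params):
        tot = 0
        for s in range(300):
            state = MIFNetworkState.at_rest(params)
            c = fire(0, state, params, np.random.default_rng(s))
            tot += c["E"] + c["I"]
        # E[total] = M_E = 23.75; binomial sd ~ 3.9/sqrt(300)
        assert tot / 300 == pytest.approx(23.75, abs=1.0)

    def test_exit_refractory_resets_to_rest(self, params):
        state = MIFNetworkState.at_rest(params)
        state.refractory[3] = True
        assert exit_refractory(3, state, params) == 0
        assert state.potential(3) == 0

    def test_exit_refractory_requires_refractory_neuron(self, params):
        state = MIFNetworkState.at_rest(params)
        with pytest.raises(RuntimeError):
            exit_refractory(3, state, params)


class TestEventRates:
    def test_quiescent_network_has_only_external_rate(self, params):
        state = MIFNetworkState.at_rest(params)
        r = total_event_rates(state, params)
        # 100 neurons x 7000 Hz = 700 events per ms
        assert r["total"] == pytest.approx(700.0)
        assert r["external"] == pytest.approx(700.0)

    def test_pending_pool_rate_uses_synaptic_time_scale(self, params):
        state = MIFNetworkState.at_rest(params)
        state.h_e[0] = 10
        r = total_event_rates(state, params)
        assert r["pending_e_on_e"] == pytest.approx(10 / 1.4)

    def test_silent_network_halts(self):
        p = make_regime("Syn", lambda_E=0.0, lambda_I=0.0)
        state = MIFNetworkState.at_rest(p)
        assert total_event_rates(state, p)["total"] == 0.0
        res = run_mif(p, 100.0, seed=0)
        assert len(res.train) == 0

    def test_negative_pool_rejected(self, params):
        state = MIFNetworkState.at_rest(params)
        state.h_e[0] = -1
        with pytest.raises(RuntimeError):
            total_event_rates(state, params)


class TestProjection:
    def test_rest_state_projects_to_origin(self, params):
        state = MIFNetworkState.at_rest(params)
        assert project_cg(state, 60, 75) == (0, 0, 0, 0)

    def test_gate_count_from_handcrafted_state(self, params):
        state = MIFNetworkState.at_rest(params)
        state.v[[2, 5, 9]] = 90
        assert project_cg(state, 60, 75)[0] == 3

    def test_gate_and_base_partition_population(self, params):
        rng = np.random.default_rng(3)
        state = MIFNetworkState.at_rest(params)
        state.v[:] = rng.integers(-66, 100, size=100)
        state.refractory[:] = rng.random(100) < 0.2
        n_ge, n_gi, _, _ = project_cg(state, 60, 75)
        gate = (~state.refractory) & (state.v >= 60)
        assert n_ge + int((~gate[:75]).sum()) == 75
        assert n_gi + int((~gate[75:]).sum()) == 25


class TestRunMif:
    def test_zero_duration_gives_empty_outputs(self, params):
        res = run_mif(params, 0.0, seed=1)
        assert len(res.train) == 0

    def test_identical_seed_identical_output(self, params):
        a = run_mif(params, 300.0, seed=5, record_events=True)
        b = run_mif(params, 300.0, seed=5, record_events=True)
        assert a.train == b.train
        assert a.projection == b.projection
        assert np.array_equal(a.events.keys, b.events.keys)

    def test_rates_physiological_and_inhibition_faster(self, syn_run):
        fr_e, fr_i = firing_rates(syn_run.train, 75, 25)
        assert 1.0 < fr_e < 100.0
        assert 1.0 < fr_i < 100.0
        assert fr_i > fr_e

    def test_pool_bookkeeping_balances(self, syn_run):
        b = syn_run.bookkeeping
        assert b["e_kicks_delivered"] - b["e_kicks_consumed"] == b["h_e_final"]
        assert b["i_kicks_delivered"] - b["i_kicks_consumed"] == b["h_i_final"]

    def test_projection_within_population_bounds(self, syn_run):
        p = syn_run.projection
        assert p.n_ge.max() <= 75 and p.n_gi.max() <= 25

    def test_summary_statistics_stable_across_seeds(self, params, syn_run):
        # batch-mean firing rates from independent seeds agree within
        # combined batch standard errors
        other = run_mif(params, 5000.0, seed=101)

        def batch_rates(train, t0, t1):
            return np.array([
                firing_rates(train, 75, 25, t_start=a, t_end=a + 1000.0)[0]
                for a in np.arange(t0, t1, 1000.0)
            ])

        b1 = batch_rates(syn_run.train, 1000.0, 10_000.0)
        b2 = batch_rates(other.train, 1000.0, 5000.0)
        se = np.hypot(b1.std(ddof=1) / np.sqrt(b1.size),
                      b2.std(ddof=1) / np.sqrt(b2.size))
        assert abs(b1.mean() - b2.mean()) < 5 * se

    def test_regime_synchrony_ordering(self):
        # Syn > Reg > Hom in spike synchrony on matched runs
        vals = {}
        for name in ("Hom", "Reg", "Syn"):
            res = run_mif(make_regime(name), 5000.0, seed=11)
            vals[name] = ssi(res.train)
        assert vals["Syn"] > vals["Reg"] > vals["Hom"]


class TestPendingPoolGreensFunction:
    def test_ensemble_mean_matches_exponential_kernel(self):
        # mean pool content for a fixed periodic kick train equals the
        # exponential Green's-function convolution of the conductance
        kicks = np.arange(5.0, 50.0, 5.0)
        samples = np.array([6.0, 12.0, 20.0, 35.0, 49.0])
        tau = 1.4
        traces = pending_pool_trace(kicks, tau, samples, n_runs=3000, seed=9)
        mean = traces.mean(axis=0)
        se = traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
        expected = np.array([
            np.exp(-(t - kicks[kicks <= t]) / tau).sum() for t in samples
        ])
        assert (np.abs(mean - expected) < 3 * se).all()
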