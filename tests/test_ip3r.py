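"""Unit and property tests of the IP3R subunit chain and its SSA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astroca.ip3r import (
    ACTIVE_STATE,
    ChannelEnsembleState,
    DKMRates,
    SubunitState,
    gating_ssa,
    seed_rng_state,
    simulate_gating,
    stationary_distribution,
    stationary_open_probability,
    subunit_generator,
)


def test_subunit_state_encoding():
    states = {SubunitState.from_index(i) for i in range(8)}
    assert len(states) == 8
    active = [s for s in states if s.active]
    assert len(active) == 1
    assert active[0] == SubunitState(True, True, False)  # X_110


def test_rates_validation():
    with pytest.raises(ValueError, match="higher affinity"):
        DKMRates(act_off=100.0)  # activating Kd above the inhibiting Kd
    with pytest.raises(ValueError, match="non-negative"):
        DKMRates(act_on=-1.0)


class TestGenerator:
    def test_structure_twelve_reversible_transitions(self, rates):
        Q = subunit_generator(0.3, 1.0, rates)
        off = Q - np.diag(np.diag(Q))
        assert np.count_nonzero(off) == 24  # 12 reversible edges
        assert np.count_nonzero((off > 0) & (off.T > 0)) == 24
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_zero_calcium_leaves_only_ip3_and_unbinding(self, rates):
        Q = subunit_generator(0.0, 1.0, rates)
        for s in range(8):
            # binding a Ca site requires nonzero Ca
            assert Q[s, s | 2] == 0.0 or (s & 2)
            if not (s & 1):
                assert Q[s, s | 1] == 0.0

    def test_negative_concentration_rejected(self, rates):
        with pytest.raises(ValueError):
            subunit_generator(-0.1, 1.0, rates)

    def test_uniform_rates_at_dissociation_constants(self):
        """With site-independent rates and each ligand at its Kd, every site
        is half-occupied and the stationary law is uniform over the cube."""
        r = DKMRates(
            ip3_on_inh_free=10.0, ip3_off_inh_free=1.0,
            ip3_on_inh_bound=10.0, ip3_off_inh_bound=1.0,
            act_on=10.0, act_off=1.0,
            inh_on_ip3_bound=5.0, inh_off_ip3_bound=1.0,
            inh_on_ip3_free=5.0, inh_off_ip3_free=1.0,
        )
        pi = stationary_distribution(ca := 1.0 / 10.0, 1.0 / 10.0, r)
        # activating site at Kd; inhibiting site Kd = 0.2, so occupancy 1/3
        p_inh = ca / (ca + 1.0 / 5.0)
        expected = np.array(
            [
                0.5 * 0.5 * (1 - p_inh) if not (s & 1) else 0.5 * 0.5 * p_inh
                for s in range(8)
            ]
        )
        assert np.allclose(pi, expected, atol=1e-10)

    @given(
        ca=st.floats(1e-4, 1e3), ip3=st.floats(1e-4, 1e3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_generator_rows_sum_to_zero(self, ca, ip3):
        Q = subunit_generator(ca, ip3, DKMRates())
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-9 * max(ca, ip3, 1.0))


class TestStationaryOpenProbability:
    def test_stationary_is_generator_null_vector(self, rates):
        pi = stationary_distribution(0.25, 10.0, rates)
        Q = subunit_generator(0.25, 10.0, rates)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(pi @ Q).max() < 1e-10

    def test_limits_vanish(self, rates):
        assert stationary_open_probability(1e-9, 10.0, rates) < 1e-6
        assert stationary_open_probability(1e6, 10.0, rates) < 1e-6

    def test_bell_shape_single_maximum(self, rates):
        ca = np.geomspace(1e-3, 1e3, 60)
        po = np.array([stationary_open_probability(c, 10.0, rates) for c in ca])
        dsign = np.sign(np.diff(po))
        changes = np.count_nonzero(np.diff(dsign[dsign != 0]) != 0)
        assert changes == 1  # rises then falls: one interior maximum
        assert 0.0 < po.max() <= 1.0

    def test_zero_ligands_collapse_to_unbound_state(self, rates):
        """Without ligands only unbinding remains and the chain is absorbed
        in the fully unoccupied state; the channel is closed."""
        pi = stationary_distribution(0.0, 0.0, rates)
        assert pi[0] == pytest.approx(1.0, abs=1e-9)
        assert stationary_open_probability(0.0, 0.0, rates) == pytest.approx(0.0)


class TestSimulateGating:
    def test_zero_duration_no_events(self, rates):
        ens = ChannelEnsembleState.resting(3)
        events, final = simulate_gating(ens, [(0.0, 1.0, 0.2)], 10.0, 0.0, 0.0, 7)
        assert events == []
        assert np.array_equal(final.states, ens.states)

    def test_same_seed_identical_event_lists(self, rates):
        ens = ChannelEnsembleState.resting(4)
        ev1, _ = simulate_gating(ens, [(0.0, 50.0, 0.3)], 10.0, 0.0, 50.0, 11)
        ev2, _ = simulate_gating(ens, [(0.0, 50.0, 0.3)], 10.0, 0.0, 50.0, 11)
        assert ev1 == ev2
        ev3, _ = simulate_gating(ens, [(0.0, 50.0, 0.3)], 10.0, 0.0, 50.0, 12)
        assert ev1 != ev3

    def test_event_list_exports_to_frame(self, rates):
        from astroca.ip3r import events_to_frame

        ens = ChannelEnsembleState.resting(4)
        events, _ = simulate_gating(ens, [(0.0, 20.0, 0.3)], 10.0, 0.0, 20.0, 11)
        df = events_to_frame(events)
        assert list(df.columns) == ["time", "cluster_id", "channel_id",
                                    "n_open_after"]
        assert len(df) == len(events)
        assert df["time"].is_monotonic_increasing

    def test_undefined_interval_rejected(self, rates):
        ens = ChannelEnsembleState.resting(2)
        with pytest.raises(ValueError, match="undefined"):
            simulate_gating(ens, [(0.0, 1.0, 0.2)], 10.0, 0.0, 2.0, 1)

    def test_open_fraction_matches_stationary(self, rates):
        """Time-averaged open fraction of a long SSA run approaches the
        stationary open probability of the master equation."""
        ca, ip3 = 0.3, 10.0
        po = stationary_open_probability(ca, ip3, rates)
        rng = np.random.default_rng(5)
        ens = ChannelEnsembleState.stationary(20, ca, ip3, rates, rng)
        events, _ = simulate_gating(ens, [(0.0, 150.0, ca)], ip3, 0.0, 150.0, 21)
        # integrate n_open over time from the event list
        t_prev, n_prev = 0.0, ens.n_open
        acc = 0.0
        for ev in events:
            acc += n_prev * (ev.time - t_prev)
            t_prev, n_prev = ev.time, ev.n_open_after
        acc += n_prev * (150.0 - t_prev)
        open_frac = acc / (150.0 * 20)
        assert open_frac == pytest.approx(po, rel=0.1)

    def test_ssa_occupancy_converges_to_master_equation(self, rates):
        """Total-variation distance between sampled subunit occupancy and the
        stationary law stays below 0.02 over a long run (~1e5 events)."""
        ca, ip3 = 0.3, 10.0
        pi = stationary_distribution(ca, ip3, rates)
        rng = np.random.default_rng(3)
        ens = ChannelEnsembleState.stationary(4, ca, ip3, rates, rng)
        states = ens.states.reshape(-1).copy()
        sub_cluster = np.zeros(states.size, dtype=np.int64)
        n_active = (ens.states == ACTIVE_STATE).sum(axis=1).astype(np.int64)
        rng_state = seed_rng_state(17)
        counts = np.zeros(8)
        t, dt, t_end = 0.0, 0.05, 1500.0
        total_transitions = 0
        while t < t_end:
            _, _, ntr = gating_ssa(
                states, sub_cluster, n_active, np.array([ca]), ip3,
                rates.as_array(), t, t + dt, rng_state, False,
            )
            total_transitions += ntr
            for s in states:
                counts[s] += 1
            t += dt
        emp = counts / counts.sum()
        tv = 0.5 * np.abs(emp - pi).sum()
        assert total_transitions > 1e5
        assert tv < 0.02
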