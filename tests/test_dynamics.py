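"""Hand-traced oracles and invariants for the per-step lesion dynamics."""

import copy
from dataclasses import replace

import numpy as np
import pytest

from lesionnet import CAUSE_APOP, CAUSE_NONE, CAUSE_PATH, DynamicsParams, run, step
from lesionnet.dynamics import (
    generate_alarms,
    init_state,
    pathological_substep,
    relay_signals,
    trigger_apoptosis,
    update_roi,
)


def fresh(g, params):
    return init_state(g, params)


class TestInitState:
    def test_full_health(self, star5):
        g, params = star5
        st = fresh(g, params)
        assert st.t == 0 and st.roi == params.roi0
        assert np.all(st.weight == 1)
        assert np.array_equal(st.S, g.degree)
        assert np.array_equal(st.s, st.S)
        assert st.cum_path == st.cum_apop == 0

    def test_max_health_scales_with_wmax(self, star5):
        g, params = star5
        st = fresh(g, replace(params, w_max=3, p_damage=0.33, p_regen=0.0))
        # hand count: hub degree 4 -> S = 12, satellites 3 each
        assert list(st.S) == [12, 3, 3, 3, 3]

    def test_empty_lesion_region_warns(self, handplaced5):
        g, params = handplaced5
        with pytest.warns(UserWarning, match="no eligible edges"):
            fresh(g, replace(params, roi0=0.01, lesion_center=(0.5, 0.5)))


class TestPathologicalSubstep:
    def test_zero_probability(self, dense20):
        g, params = dense20
        params = replace(params, p_damage=0.0, roi0=2.0)
        st = fresh(g, params)
        visited, damaged = pathological_substep(st, g, params, np.random.default_rng(0))
        assert visited == g.m and damaged == 0
        assert np.all(st.weight == 1)

    def test_certain_damage(self, dense20):
        g, params = dense20
        params = replace(params, p_damage=1.0, roi0=2.0)
        st = fresh(g, params)
        visited, damaged = pathological_substep(st, g, params, np.random.default_rng(0))
        assert visited == damaged == g.m
        assert np.all(st.weight == 0)
        assert np.all(st.damage_cause == CAUSE_PATH)
        assert np.all(st.path_hit)
        assert np.all(st.s == 0)

    def test_binomial_mean(self, dense20):
        """Damage counts match the binomial oracle: mean within 3 SE."""
        g, params = dense20
        params = replace(params, p_damage=0.33, roi0=2.0)
        rng = np.random.default_rng(1234)
        base = fresh(g, params)
        reps = 4000
        total = 0
        for _ in range(reps):
            st = copy.deepcopy(base)
            _, damaged = pathological_substep(st, g, params, rng)
            total += damaged
        p, m = 0.33, g.m
        se = np.sqrt(m * p * (1 - p) / reps)
        assert abs(total / reps - p * m) < 3 * se


def test_update_roi_arithmetic(chain3):
    g, params = chain3
    params = replace(params, alpha=0.12, roi0=0.05)
    st = fresh(g, params)
    assert update_roi(st, 0.0, params) == pytest.approx(0.05)
    assert update_roi(st, 0.5, params) == pytest.approx(0.053)
    st.roi = 0.05
    update_roi(st, 1.0, params)
    assert st.roi - 0.05 == pytest.approx(0.006)
    with pytest.raises(ValueError):
        update_roi(st, 1.5, params)


class TestAlarms:
    def damaged_star(self, star5):
        """Hub with 3 of its 4 edges dead pathologically; only its alarm set."""
        g, params = star5
        st = fresh(g, params)
        dead = [j for j, (u, v) in enumerate(g.edges) if v != 1][:3]
        st.weight[dead] = 0
        st.damage_cause[dead] = CAUSE_PATH
        st.path_hit[0] = True
        st.recompute_health(g)
        return g, params, st

    def test_no_emitters_when_undamaged(self, star5):
        g, params = star5
        st = fresh(g, params)
        assert generate_alarms(st, g, params).size == 0
        assert np.all(st.signal_acc == 0)

    def test_hub_emits_along_live_edge_only(self, star5):
        g, params, st = self.damaged_star(star5)
        emitters = generate_alarms(st, g, replace(params, tau_al=0.7))
        assert list(emitters) == [0]  # 1/4 < 0.7
        # satellite 1 holds the only live edge; dead edges carry amplitude 0
        assert list(st.signal_acc) == [0, 1, 0, 0, 0]

    def test_higher_tau_al_is_superset(self, rgg400):
        g = rgg400
        params = DynamicsParams()
        rng = np.random.default_rng(5)
        st = fresh(g, params)
        for _ in range(12):
            pathological_substep(st, g, params, rng)
            update_roi(st, 0.33, params)
        lo = set(generate_alarms(copy.deepcopy(st), g, replace(params, tau_al=0.1)))
        hi = set(generate_alarms(copy.deepcopy(st), g, replace(params, tau_al=0.9)))
        assert lo <= hi and len(hi) > len(lo)


class TestRelay:
    def test_no_signal_no_relay(self, chain3):
        g, params = chain3
        st = fresh(g, params)
        assert relay_signals(st, g).size == 0

    def test_chain_cascade(self, chain3):
        """b relays once its sum reaches s_b = 2; endpoints then echo back."""
        g, params = chain3
        st = fresh(g, params)
        st.signal_acc[1] = 1.0
        assert relay_signals(st, g).size == 0  # 1 < 2
        st.signal_acc[1] = 2.0
        relayers = relay_signals(st, g)
        # b fires to a and c; a and c (acc 1 >= s 1) each relay back once
        assert sorted(relayers) == [0, 1, 2]
        assert list(st.signal_acc) == [1, 4, 1]

    def test_zero_health_node_absorbs(self, chain3):
        g, params = chain3
        st = fresh(g, params)
        st.weight[:] = 0
        st.recompute_health(g)
        st.signal_acc[1] = 0.5
        relayers = relay_signals(st, g)
        assert list(relayers) == [1]  # threshold 0 is reached ...
        assert list(st.signal_acc) == [0, 0.5, 0]  # ... but forwards amplitude 0


class TestApoptosis:
    def test_no_signal_no_firing(self, star5):
        g, params = star5
        st = fresh(g, params)
        fired, units = trigger_apoptosis(st, g, params, np.random.default_rng(0))
        assert fired.size == 0 and units == 0

    def test_radius_zero_kills_own_edges(self, star5):
        g, params = star5
        params = replace(params, c_bf=0.0, tau_bf=0.5)
        st = fresh(g, params)
        st.signal_acc[0] = 2.0  # = tau_bf * S_hub
        fired, units = trigger_apoptosis(st, g, params, np.random.default_rng(0))
        assert list(fired) == [0] and units == 4
        assert np.all(st.weight == 0)
        assert np.all(st.damage_cause == CAUSE_APOP)
        assert st.apoptotic_node[0] and not st.apoptotic_node[1:].any()
        assert st.signal_acc[0] == 0

    def test_simultaneous_evaluation(self, chain3):
        """Both ends fire against pre-apoptosis accumulators even though one
        region reset would have silenced the other."""
        g, params = chain3
        params = replace(params, c_bf=20.0, tau_bf=0.5)
        st = fresh(g, params)
        st.signal_acc[[0, 2]] = 0.6  # S = 1 at the ends
        fired, _ = trigger_apoptosis(st, g, params, np.random.default_rng(0))
        assert sorted(fired) == [0, 2]
        assert st.apoptotic_node.all()

    def test_p_apoptosis_zero_never_fires(self, star5):
        g, params = star5
        params = replace(params, p_apoptosis=0.0)
        st = fresh(g, params)
        st.signal_acc[:] = 10.0
        fired, units = trigger_apoptosis(st, g, params, np.random.default_rng(0))
        assert fired.size == 0 and units == 0

    def test_pair_kill_mode_spares_long_edges(self, star5):
        g, params = star5
        params = replace(params, c_bf=0.5, kill_mode="pair")  # radius 0.025
        st = fresh(g, params)
        st.signal_acc[0] = 2.0
        fired, units = trigger_apoptosis(st, g, params, np.random.default_rng(0))
        assert list(fired) == [0] and units == 0  # no edge lies inside the disk
        assert np.all(st.weight == 1)


class TestStepAndRun:
    def test_vacuous_step(self, handplaced5):
        g, params = handplaced5
        with pytest.warns(UserWarning):
            st = init_state(g, replace(params, roi0=0.01, lesion_center=(0.5, 0.5)))
        rec = step(st, g, replace(params, roi0=0.01, lesion_center=(0.5, 0.5)),
                   np.random.default_rng(0))
        assert rec.visited == 0 and rec.R_I == 0.0
        assert rec.roi_after == 0.01 and rec.cum_total == 0

    def test_no_damage_arrests_at_window(self, dense20):
        g, params = dense20
        params = replace(params, p_damage=0.0)
        ts, st, arrested = run(g, params, 50, 0, arrest_window=3)
        assert arrested and len(ts) == 3
        assert ts.records[-1].cum_total == 0

    def test_fuel_exhaustion_arrests(self, chain3):
        g, params = chain3
        params = replace(params, p_damage=1.0, roi0=2.0)
        ts, st, arrested = run(g, params, 50, 0)
        assert arrested and ts.records[0].damaged_path == 2

    def test_determinism(self, rgg400):
        g = rgg400
        params = DynamicsParams(c_bf=0.8)
        a, _, _ = run(g, params, 40, np.random.default_rng(7))
        b, _, _ = run(g, params, 40, np.random.default_rng(7))
        assert a.to_frame().equals(b.to_frame())

    @pytest.mark.parametrize("w_max,p_damage", [(1, 0.33), (3, 0.4)])
    def test_damage_accounting_conservation(self, rgg400, w_max, p_damage):
        """cum_path + cum_apop equals total health units lost; every fully
        dead edge carries a first-touch cause mark."""
        g = rgg400
        params = DynamicsParams(w_max=w_max, p_damage=p_damage, c_bf=0.8)
        ts, st, _ = run(g, params, 30, 3)
        lost = int((w_max - st.weight).sum())
        assert st.cum_path + st.cum_apop == lost
        assert np.all(st.damage_cause[st.weight == 0] != CAUSE_NONE)
        rec = ts.records[-1]
        assert rec.cum_total == rec.cum_path + rec.cum_apop == lost

    def test_step_record_invariants(self, rgg400):
        g = rgg400
        params = DynamicsParams(c_bf=0.8)
        ts, _, _ = run(g, params, 40, 11)
        prev_total = 0
        for rec in ts.records:
            assert 0.0 <= rec.R_I <= 1.0
            assert rec.damaged_path <= rec.visited
            assert rec.cum_total >= prev_total
            prev_total = rec.cum_total

    def test_regeneration_can_restore_weight(self, dense20):
        g, params = dense20
        params = replace(params, p_damage=0.5, p_regen=1.0, roi0=2.0)
        st = fresh(g, params)
        rng = np.random.default_rng(2)
        for _ in range(5):
            step(st, g, params, rng)
        assert np.all(st.weight >= 0) and np.all(st.weight <= 1)
        assert st.weight.sum() > 0  # certain regeneration keeps edges alive
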