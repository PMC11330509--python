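"""POMDP agent components and simulation-level properties."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from adaptbias import agents, glm, task
from adaptbias.agents import (AgentParams, BeliefState, ValueTable,
                              compute_belief, compute_expected_values,
                              compute_extended_memory, compute_memory_state,
                              simulate_agent, softmax_choice, update_values)


class TestBelief:
    def test_forced_zero_estimate_gives_even_belief(self):
        b = compute_belief(0.5, 0.3, s_hat=0.0)
        assert b.p_right == pytest.approx(0.5)
        assert b.p_left + b.p_right == pytest.approx(1.0)

    def test_noiseless_limit_is_certain(self):
        b = compute_belief(1.0, 1e-6, s_hat=1.0)
        assert b.p_right == pytest.approx(1.0)

    def test_matches_normal_cdf_oracle(self):
        # independent oracle: scipy's normal CDF at s_hat / sigma
        b = compute_belief(0.0, 0.3, s_hat=0.0625)
        assert b.p_right == pytest.approx(norm.cdf(0.0625 / 0.3), rel=1e-12)
        assert b.p_right == pytest.approx(0.58251564682, rel=1e-9)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            compute_belief(0.0, 0.0)


class TestMemory:
    def test_one_back_rewarded_choices(self):
        assert compute_memory_state("L", 1, 0.07) == (0.07, 0.0)
        assert compute_memory_state("R", 1, 0.07) == (0.0, 0.07)
        assert compute_memory_state("L", 0, 0.07) == (0.0, 0.0)
        assert compute_memory_state("none", 1, 0.07) == (0.0, 0.0)
        assert compute_memory_state("R", 1, 0.0) == (0.0, 0.0)

    def test_memory_strength_bounds(self):
        with pytest.raises(ValueError):
            compute_memory_state("L", 1, 1.5)

    def test_extended_memory_series(self):
        # 1-back rewarded left only: weight exp(0) = 1
        assert compute_extended_memory([None, None, "L"], 0.1, 1.0) == \
            pytest.approx((0.1, 0.0))
        # rewarded left at lags 1 and 2: m0 * (1 + e^{-1/tau})
        m = compute_extended_memory(["L", "L"], 0.1, 1.0)
        assert m[0] == pytest.approx(0.1 * (1 + math.exp(-1)))
        assert m[1] == 0.0
        # tiny tau: only the 1-back trial survives
        m = compute_extended_memory(["R", None], 0.1, 1e-9)
        assert m == pytest.approx((0.0, 0.0))

    def test_extended_memory_invalid_tau(self):
        with pytest.raises(ValueError):
            compute_extended_memory(["L"], 0.1, 0.0)


class TestExpectedValues:
    def test_zero_table_gives_zero_values(self):
        b = BeliefState(0.3, 0.7, 0.07, 0.0)
        assert compute_expected_values(b, ValueTable(), "multi") == (0.0, 0.0)

    def test_identity_pairing(self):
        q = np.zeros((2, 4))
        q[1, 1] = 1.0  # q_{R, P_R}
        b = BeliefState(0.0, 1.0)
        assert compute_expected_values(b, ValueTable(q), "multi") == (0.0, 1.0)

    def test_hand_dot_product(self):
        q = np.array([[0.2, -0.1, 0.5, -0.3],
                      [0.4, 0.8, -0.2, 0.6]])
        b = BeliefState(0.3, 0.7, 0.07, 0.0)
        ql = 0.3 * 0.2 + 0.7 * -0.1 + 0.07 * 0.5
        qr = 0.3 * 0.4 + 0.7 * 0.8 + 0.07 * -0.2
        got = compute_expected_values(b, ValueTable(q), "multi")
        assert got == pytest.approx((ql, qr))
        # single variant ignores the memory block
        got_single = compute_expected_values(b, ValueTable(q), "single")
        assert got_single == pytest.approx((0.3 * 0.2 + 0.7 * -0.1,
                                            0.3 * 0.4 + 0.7 * 0.8))


class TestSoftmax:
    def test_equal_values_even_odds(self):
        _, p = softmax_choice(0.4, 0.4, 0.36, np.random.default_rng(0))
        assert p == pytest.approx(0.5)

    def test_one_temperature_gap(self):
        _, p = softmax_choice(0.0, 0.36, 0.36, np.random.default_rng(0))
        assert p == pytest.approx(1 / (1 + math.exp(-1)))

    def test_best_fit_temperature_unit_gap(self):
        _, p = softmax_choice(0.0, 1.0, 0.36, np.random.default_rng(0))
        assert p == pytest.approx(1 / (1 + math.exp(-1 / 0.36)))

    def test_numerically_stable_for_large_gaps(self):
        _, p = softmax_choice(-500.0, 500.0, 0.01, np.random.default_rng(0))
        assert p == 1.0

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            softmax_choice(0, 0, 0.0)


class TestUpdate:
    def test_zero_learning_rate_keeps_table(self):
        b = BeliefState(0.4, 0.6)
        # alpha bounds exclude exact 0; delta = 0 gives no change either
        q = np.array([[0.5, 0.5, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0]])
        out, delta = update_values(ValueTable(q), b, "R", 1, 0.9, 0.9, "multi")
        assert delta == pytest.approx(0.0)
        assert np.allclose(out.q, q)

    def test_one_step_convergence(self):
        b = BeliefState(1.0, 0.0)
        out, delta = update_values(ValueTable(), b, "L", 1, 1.0, 1.0, "single")
        assert delta == 1.0
        assert out.q[0, 0] == 1.0
        assert np.count_nonzero(out.q) == 1

    def test_hand_computed_negative_update(self):
        q = np.zeros((2, 4))
        q[1, :] = [0.5, 0.5, 0.0, 0.0]  # makes Q_R = 0.5 with any belief
        b = BeliefState(0.4, 0.6, 0.07, 0.0)
        out, delta = update_values(ValueTable(q), b, "R", 0, 0.96, 0.97,
                                   "multi")
        assert delta == pytest.approx(-0.5)
        assert out.q[1, 0] == pytest.approx(0.5 - 0.97 * 0.4 * 0.5)
        assert out.q[1, 1] == pytest.approx(0.5 - 0.97 * 0.6 * 0.5)
        assert out.q[1, 2] == pytest.approx(0.0 - 0.97 * 0.07 * 0.5)
        assert out.q[1, 3] == pytest.approx(0.0)
        assert np.allclose(out.q[0], 0.0)  # unchosen row untouched

    def test_invalid_choice(self):
        with pytest.raises(ValueError):
            update_values(ValueTable(), BeliefState(0.5, 0.5), "none", 0,
                          0.5, 0.5, "multi")


class TestSimulation:
    def test_single_nested_in_multi_at_zero_memory(self):
        sched = task.SessionSchedule([task.environment("neutral")] * 3)
        sessions = agents.make_sessions(sched, 200, seed=50)
        p_multi = AgentParams(variant="multi", memory_strength=0.0)
        p_single = AgentParams(variant="single")
        tm, trm = simulate_agent(p_multi, sessions, seed=51)
        ts, trs = simulate_agent(p_single, sessions, seed=51)
        assert (tm["choice"] == ts["choice"]).all()
        pd.testing.assert_frame_equal(trm.drop(columns=["m_left", "m_right"]),
                                      trs.drop(columns=["m_left", "m_right"]))

    def test_delta_identity_and_q_pre_definition(self, multi_neutral):
        trials, trace = multi_neutral
        assert np.allclose(trace["delta"],
                           trials["outcome"] - trace["Q_C"])
        p_r = trace["p_right_choice"]
        assert np.allclose(trace["Q_pre"],
                           (1 - p_r) * trace["Q_L"] + p_r * trace["Q_R"])
        assert np.allclose(trace["Q_pre"],
                           trace["Q_pre_perception"] + trace["Q_pre_memory"])

    def test_memory_reset_at_session_boundaries(self, multi_neutral):
        trials, trace = multi_neutral
        first = trace["trial_index"] == 0
        assert np.allclose(trace.loc[first, ["m_left", "m_right"]], 0.0)
        # within a session, memory is lambda after a rewarded trial
        lam = AgentParams.best_fit("multi").memory_strength
        rewarded_prev = (trials["outcome"].shift() == 1) & ~first
        m_tot = trace["m_left"] + trace["m_right"]
        assert np.allclose(m_tot[rewarded_prev], lam)
        assert np.allclose(m_tot[~rewarded_prev & ~first], 0.0)

    def test_simulation_reproducible(self):
        sched = task.SessionSchedule([task.environment("repeating")] * 2)
        sessions = agents.make_sessions(sched, 100, seed=60)
        p = AgentParams.best_fit("multi")
        t1, tr1 = simulate_agent(p, sessions, seed=61)
        t2, tr2 = simulate_agent(p, sessions, seed=61)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_extended_memory_accumulates_both_sides(self):
        sched = task.SessionSchedule([task.environment("neutral")])
        sessions = agents.make_sessions(sched, 300, seed=62)
        p = AgentParams(variant="extended", m0=0.07, tau=2.0)
        _, trace = simulate_agent(p, sessions, seed=63)
        both = (trace["m_left"] > 0) & (trace["m_right"] > 0)
        assert both.any()

    @pytest.mark.parametrize("fixture", ["multi_neutral", "single_neutral"])
    def test_confidence_effect(self, fixture, request):
        """Repetition of rewarded choices is stronger after low-contrast
        (low-confidence) decisions than after high-contrast ones."""
        trials, _ = request.getfixturevalue(fixture)
        t = trials.reset_index(drop=True)
        prev = t.shift()
        ok = ((t["session_id"] == prev["session_id"])
              & (prev["outcome"] == 1))
        rep = (t["choice"] == prev["choice"])[ok]
        prev_c = prev.loc[ok, "contrast"]
        p_rep_low = rep[prev_c <= 0.0625].mean()
        p_rep_high = rep[prev_c >= 0.5].mean()
        assert p_rep_low > p_rep_high


class TestParams:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            AgentParams(sigma=0.01)
        with pytest.raises(ValueError):
            AgentParams(temperature=0.0)
        with pytest.raises(ValueError):
            AgentParams(memory_strength=1.2)
        with pytest.raises(ValueError):
            AgentParams(variant="duo")

    def test_best_fit_presets(self):
        m = AgentParams.best_fit("multi")
        assert (m.sigma, m.alpha_pos, m.alpha_neg, m.temperature,
                m.memory_strength) == (0.09, 0.96, 0.97, 0.36, 0.07)
        s = AgentParams.best_fit("single")
        assert (s.sigma, s.alpha_pos, s.alpha_neg, s.temperature) == \
            (0.1, 0.41, 1.0, 0.4)
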