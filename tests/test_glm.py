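"""Choice-history GLM: design coding, fitting, and model-free analyses."""

import numpy as np
import pandas as pd
import pytest

from adaptbias import glm, task
from adaptbias.glm import (HistoryKernelFit, build_design_matrix,
                           conditioned_psychometric, fit_choice_glm,
                           repetition_by_condition, simulate_from_kernels)


def _table(rows):
    return pd.DataFrame(rows)


def _trials_from_lists(sides, choices, contrasts=None, session_id=0):
    n = len(sides)
    contrasts = contrasts if contrasts is not None else [1.0] * n
    return _table([
        dict(session_id=session_id, trial_index=i, side=sides[i],
             contrast=abs(contrasts[i]),
             signed_contrast=contrasts[i] if sides[i] == "R" else -contrasts[i],
             choice=choices[i],
             outcome=int(choices[i] == sides[i]))
        for i in range(n)])


class TestDesignMatrix:
    def test_seven_rewarded_rightward_predecessors(self):
        trials = _trials_from_lists(["R"] * 8, ["R"] * 8)
        d = build_design_matrix(trials)
        assert d.X.shape[0] == 1
        nc = d.n_contrast
        assert np.allclose(d.X[0, nc:nc + 7], 1.0)   # r+ all +1
        assert np.allclose(d.X[0, nc + 7:], 0.0)     # r- all 0

    def test_one_back_incorrect_left_choice(self):
        sides = ["R"] * 7 + ["R", "L"]
        choices = ["R"] * 7 + ["L", "L"]  # 8th trial: incorrect left
        trials = _trials_from_lists(sides, choices)
        d = build_design_matrix(trials)
        row = d.X[-1]
        nc = d.n_contrast
        assert row[nc] == 0.0        # r+(1) zero: 1-back was incorrect
        assert row[nc + 7] == -1.0   # r-(1) = -1: incorrect left

    def test_short_session_yields_no_rows(self):
        trials = _trials_from_lists(["R"] * 7, ["R"] * 7)
        d = build_design_matrix(trials)
        assert d.X.shape[0] == 0

    def test_histories_do_not_cross_sessions(self):
        a = _trials_from_lists(["R"] * 10, ["R"] * 10, session_id=0)
        b = _trials_from_lists(["L"] * 10, ["L"] * 10, session_id=1)
        d = build_design_matrix(pd.concat([a, b], ignore_index=True))
        # 3 rows per session; second session's history is all leftward
        assert d.X.shape[0] == 6
        nc = d.n_contrast
        assert np.allclose(d.X[3:, nc:nc + 7], -1.0)

    def test_unordered_trials_raise(self):
        trials = _trials_from_lists(["R"] * 9, ["R"] * 9)
        trials.loc[5, "trial_index"] = 3
        with pytest.raises(ValueError, match="strictly increasing"):
            build_design_matrix(trials)

    def test_timeout_trials_excluded_from_response_and_history(self):
        sides = ["R"] * 9
        choices = ["R"] * 7 + ["none", "R"]
        trials = _trials_from_lists(sides, choices)
        trials.loc[7, "outcome"] = 0
        d = build_design_matrix(trials)
        # the 'none' trial contributes no row...
        assert d.X.shape[0] == 1
        nc = d.n_contrast
        # ...and its lag-1 regressors are zero for the final trial
        assert d.X[0, nc] == 0.0 and d.X[0, nc + 7] == 0.0


@pytest.fixture(scope="module")
def kernel_truth():
    levels = np.array([-1, -0.5, -0.25, -0.125, -0.0625, 0, 0.0625, 0.125,
                       0.25, 0.5, 1.0])
    w_contrast = dict(zip(levels, 4.0 * levels))
    return HistoryKernelFit(
        w_contrast=w_contrast,
        w_correct=np.array([0.1, 0.35, 0.25, 0.15, 0.1, 0.05, 0.0]),
        w_error=np.array([-0.2, -0.1, 0.0, 0.0, 0.0, 0.0, 0.0]),
        w0=0.05, penalty=0.0)


@pytest.fixture(scope="module")
def recovered(kernel_truth):
    env = task.environment("neutral")
    sched = task.SessionSchedule([env] * 30)
    from adaptbias import agents
    sessions = agents.make_sessions(sched, 400, seed=70)
    rows = []
    for sid, (e, seq) in enumerate(sessions):
        for i, (side, c) in enumerate(seq):
            rows.append(dict(session_id=sid, trial_index=i, side=side,
                             contrast=c,
                             signed_contrast=c if side == "R" else -c,
                             choice="R", outcome=0))
    stim = pd.DataFrame(rows)
    sim = simulate_from_kernels(kernel_truth, stim, seed=71)
    design = build_design_matrix(sim)
    fit = fit_choice_glm(design, seed=72)  # full 10-fold CV lasso path
    return fit


class TestFitting:
    def test_parameter_recovery_with_cv_lasso(self, kernel_truth, recovered):
        truth = np.concatenate([kernel_truth.w_correct,
                                kernel_truth.w_error])
        est = np.concatenate([recovered.w_correct, recovered.w_error])
        r = np.corrcoef(truth, est)[0, 1]
        assert r > 0.9
        assert np.abs(est - truth).max() < 0.12

    def test_history_blind_responder_shrinks_kernels(self):
        rng = np.random.default_rng(80)
        env = task.environment("neutral")
        seq = task.generate_stimulus_sequence(env, 8000, seed=81)
        rows = []
        for i, (side, c) in enumerate(seq):
            sc = c if side == "R" else -c
            p = 1 / (1 + np.exp(-6 * sc))
            ch = "R" if rng.random() < p else "L"
            rows.append(dict(session_id=0, trial_index=i, side=side,
                             contrast=c, signed_contrast=sc, choice=ch,
                             outcome=int(ch == side)))
        design = build_design_matrix(pd.DataFrame(rows))
        fit = fit_choice_glm(design, penalty=1e-3)
        assert np.abs(fit.w_correct).max() < 0.1
        assert np.abs(fit.w_error).max() < 0.15

    def test_left_right_relabeling_negates_weights(self, multi_neutral):
        trials, _ = multi_neutral
        sub = trials[trials.session_id < 10].copy()
        design = build_design_matrix(sub)
        fit = fit_choice_glm(design, penalty=0.0)
        flip = {"L": "R", "R": "L"}
        mirrored = sub.assign(
            side=sub["side"].map(flip), choice=sub["choice"].map(flip),
            signed_contrast=-sub["signed_contrast"])
        design_m = build_design_matrix(mirrored)
        fit_m = fit_choice_glm(design_m, penalty=0.0)
        assert np.allclose(fit_m.w_correct, fit.w_correct, atol=1e-4)
        assert np.allclose(fit_m.w_error, fit.w_error, atol=1e-4)
        assert fit_m.w0 == pytest.approx(-fit.w0, abs=1e-4)
        # contrast weights mirror across the sign of the level
        w = np.array(list(fit.w_contrast.values()))
        w_m = np.array(list(fit_m.w_contrast.values()))
        assert np.allclose(w_m, -w[::-1], atol=1e-4)

    def test_huge_penalty_zeroes_history_weights(self, multi_neutral):
        trials, _ = multi_neutral
        sub = trials[trials.session_id < 5]
        design = build_design_matrix(sub)
        fit = fit_choice_glm(design, penalty=10.0)
        assert np.allclose(fit.w_correct, 0.0, atol=1e-6)
        assert np.allclose(fit.w_error, 0.0, atol=1e-6)
        # unpenalised contrast weights survive
        assert np.abs(list(fit.w_contrast.values())).max() > 1.0

    def test_degenerate_column_reported(self):
        trials = _trials_from_lists(["R"] * 30, ["R"] * 30)
        design = build_design_matrix(trials)
        with pytest.raises(ValueError, match="degenerate"):
            fit_choice_glm(design, penalty=0.0)


class TestConditionedPsychometric:
    def test_history_blind_chooser_has_flat_difference(self):
        rng = np.random.default_rng(90)
        env = task.environment("neutral")
        seq = task.generate_stimulus_sequence(env, 20000, seed=91)
        rows = []
        for i, (side, c) in enumerate(seq):
            sc = c if side == "R" else -c
            ch = "R" if rng.random() < 1 / (1 + np.exp(-6 * sc)) else "L"
            rows.append(dict(session_id=0, trial_index=i, side=side,
                             contrast=c, signed_contrast=sc, choice=ch,
                             outcome=int(ch == side)))
        table = conditioned_psychometric(pd.DataFrame(rows))
        assert np.nanmax(np.abs(table["difference"])) < 0.08

    def test_repeating_environment_bias_largest_at_low_contrast(self):
        """In the repeating environment the multi-trial agent repeats its
        previous rewarded choice, most strongly at low contrast."""
        from adaptbias import agents
        sched = task.SessionSchedule([task.environment("repeating")] * 60)
        sessions = agents.make_sessions(sched, 400, seed=97)
        params = agents.AgentParams.best_fit("multi")
        trials, _ = agents.simulate_agent(params, sessions, seed=98)
        table = conditioned_psychometric(trials[trials.session_id >= 5])
        diff = table["difference"]
        low = diff[np.abs(diff.index) <= 0.0625]
        high = diff[np.abs(diff.index) >= 0.5]
        assert (low > 0).all()
        assert low.mean() > high.mean()

    def test_mirror_symmetry(self, multi_neutral):
        trials, _ = multi_neutral
        sub = trials[trials.session_id < 15]
        table = conditioned_psychometric(sub)
        flip = {"L": "R", "R": "L"}
        mirrored = sub.assign(side=sub["side"].map(flip),
                              choice=sub["choice"].map(flip),
                              signed_contrast=-sub["signed_contrast"])
        table_m = conditioned_psychometric(mirrored)
        got = table_m["difference"].to_numpy()[::-1]
        assert np.allclose(got, table["difference"].to_numpy(), atol=1e-12)


class TestRepetitionByCondition:
    def test_perfect_alternator_never_repeats(self):
        sides = ["R", "L"] * 20
        choices = ["R", "L"] * 20
        trials = _trials_from_lists(sides, choices)
        out = repetition_by_condition(trials, "nback", max_lag=2)
        assert out.loc[out.lag == 1, "p_repeat"].iloc[0] == 0.0

    def test_two_back_exceeds_one_back_for_multi_agent(self, multi_neutral):
        trials, _ = multi_neutral
        out = repetition_by_condition(trials, "nback", max_lag=2)
        p1 = out.loc[out.lag == 1, "p_repeat"].iloc[0]
        p2 = out.loc[out.lag == 2, "p_repeat"].iloc[0]
        assert p2 > p1

    def test_unknown_condition_raises(self, multi_neutral):
        trials, _ = multi_neutral
        with pytest.raises(ValueError, match="unknown condition"):
            repetition_by_condition(trials, "weekday")

    def test_four_location_contrast_effect_without_location_effect(self):
        """POMDP choices depend on previous contrast but not on whether the
        previous stimulus appeared at the same or different altitude."""
        from adaptbias import agents
        env = task.EnvironmentSpec("custom", p_repeat=0.5,
                                   vertical_locations=("low", "high"))
        sched = task.SessionSchedule([env] * 100)
        sessions = agents.make_sessions(sched, 400, seed=95)
        params = agents.AgentParams.best_fit("multi")
        trials, _ = agents.simulate_agent(params, sessions, seed=96)
        out = repetition_by_condition(trials, "previous_contrast_and_location")
        out = out.set_index(["prev_contrast_bin", "location"])["p_repeat"]
        # previous-contrast effect present for both location bins
        assert out["low", "same"] > out["high", "same"]
        assert out["low", "different"] > out["high", "different"]
        # location effect absent (much smaller than the contrast effect)
        contrast_effect = (out["low"].mean() - out["high"].mean())
        location_effect = abs(out.loc[:, "same"].mean()
                              - out.loc[:, "different"].mean())
        assert contrast_effect > 0.02
        assert location_effect < contrast_effect / 2

    def test_error_run_counts(self):
        # choices repeat after errors in this hand-built sequence
        sides = ["R"] * 12
        choices = ["L", "L", "L", "R", "R", "L", "L", "R", "R", "R", "R", "R"]
        trials = _trials_from_lists(sides, choices)
        out = repetition_by_condition(trials, "error_run", max_run=2)
        row1 = out[out.n_errors == 1].iloc[0]
        row2 = out[out.n_errors == 2].iloc[0]
        # exactly 1 preceding error: trials 1 (L->L) and 6 (L->L)
        assert row1["n"] == 2
        assert row1["p_repeat"] == 1.0
        # exactly 2 preceding errors: trials 2 (L->L) and 7 (L->R)
        assert row2["n"] == 2
        assert row2["p_repeat"] == 0.5
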