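"""Probabilistic choice model: lasso logistic regression with history kernels.

The probability of a rightward choice on trial ``i`` is modelled as
``P(R) = 1 / (1 + exp(-z))`` with

``z(i) = sum_c w_c I_c(i) + sum_{n=1..7} [w_n+ r+(i-n) + w_n- r-(i-n)] + w0``

where ``I_c`` one-hot encodes the signed contrast level, ``r+`` is the
signed direction (+1 right, -1 left) of the n-back choice when that choice
was correct and 0 otherwise, and ``r-`` mirrors it for incorrect choices.
The history weights ``w_n+`` / ``w_n-`` form the correct/error choice
history kernels.  History weights are L1-penalised with the penalty chosen
by 10-fold cross-validated deviance; intercept and contrast weights are
unpenalised by default (set ``penalize="all"`` for a glmnet-style uniform
penalty on everything but the intercept).

The module also provides model-free history analyses: psychometric curves
conditioned on the previous rewarded choice direction and binned
repetition probabilities (previous contrast x spatial location for the
4-location task, n-back repetition, and repetition as a function of
consecutive preceding errors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

SIDE_SIGN = {"L": -1.0, "R": 1.0}


@dataclass
class DesignMatrix:
    """Design matrix of the probabilistic choice model.

    ``X`` holds one column per signed-contrast level followed by the
    ``n_back`` correct-choice and ``n_back`` error-choice history
    regressors (the intercept is added by the fitting routine); ``y`` is
    the choice-is-right indicator.  ``session_id`` tracks the source
    session of every row.
    """

    X: np.ndarray
    y: np.ndarray
    contrast_levels: np.ndarray
    n_back: int
    session_id: np.ndarray
    column_names: list

    @property
    def n_contrast(self) -> int:
        return len(self.contrast_levels)


@dataclass
class HistoryKernelFit:
    """Fitted weights of the probabilistic choice model (log-odds units)."""

    w_contrast: dict
    w_correct: np.ndarray
    w_error: np.ndarray
    w0: float
    penalty: float
    cv_folds: int | None = None
    cv_deviance: dict | None = None

    def summary_vector(self) -> np.ndarray:
        """Contrast weights followed by the correct kernel (fitting order)."""
        return np.concatenate([list(self.w_contrast.values()), self.w_correct])


def build_design_matrix(trials: pd.DataFrame, n_back: int = 7,
                        contrast_levels=None) -> DesignMatrix:
    """Assemble the choice-GLM design matrix from ordered trial records.

    Trials must be ordered with strictly increasing ``trial_index`` within
    each session; histories never cross session boundaries and the first
    ``n_back`` trials of every session are dropped (incomplete history).
    Timed-out trials (``choice == "none"``) contribute neither a response
    row nor a history regressor (both ``r+`` and ``r-`` are 0 at their lag).
    """
    required = {"session_id", "trial_index", "signed_contrast", "choice", "outcome"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    for sid, grp in trials.groupby("session_id", sort=False):
        idx = grp["trial_index"].to_numpy()
        if len(idx) > 1 and not (np.diff(idx) > 0).all():
            raise ValueError(f"trial_index not strictly increasing in session {sid!r}")

    if contrast_levels is None:
        contrast_levels = np.sort(trials["signed_contrast"].unique())
    else:
        contrast_levels = np.asarray(contrast_levels, float)

    sign = trials["choice"].map(SIDE_SIGN).fillna(0.0).to_numpy()
    outcome = trials["outcome"].to_numpy()
    valid_choice = trials["choice"].isin(("L", "R")).to_numpy()
    rplus = np.where(valid_choice & (outcome == 1), sign, 0.0)
    rminus = np.where(valid_choice & (outcome == 0), sign, 0.0)

    sess = trials["session_id"].to_numpy()
    pos = np.concatenate([np.arange(n) for n in
                          trials.groupby("session_id", sort=False).size()])

    hist = np.zeros((len(trials), 2 * n_back))
    for n in range(1, n_back + 1):
        rows = np.where(pos >= n)[0]
        hist[rows, n - 1] = rplus[rows - n]
        hist[rows, n_back + n - 1] = rminus[rows - n]

    keep = (pos >= n_back) & valid_choice
    contrast_cols = (trials["signed_contrast"].to_numpy()[:, None]
                     == contrast_levels[None, :]).astype(float)
    X = np.hstack([contrast_cols, hist])[keep]
    y = (trials["choice"].to_numpy() == "R").astype(float)[keep]
    names = ([f"contrast_{c:+g}" for c in contrast_levels]
             + [f"correct_{n}" for n in range(1, n_back + 1)]
             + [f"error_{n}" for n in range(1, n_back + 1)])
    return DesignMatrix(X=X, y=y, contrast_levels=np.asarray(contrast_levels),
                        n_back=n_back, session_id=sess[keep],
                        column_names=names)


def _deviance(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def _fit_at_penalty(X, y, penalty, penalized_mask):
    """L1-penalised logistic fit; returns (coef, intercept).

    ``penalty`` is the per-observation L1 weight on the masked columns.
    The unpenalised case goes through scikit-learn's LBFGS solver; the
    penalised case through statsmodels' L1-constrained MLE, which accepts
    a per-coefficient penalty vector.
    """
    if penalty == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                                 tol=1e-8)
        clf.fit(X, y)
        return clf.coef_[0].copy(), float(clf.intercept_[0])
    import statsmodels.api as sm
    Xc = sm.add_constant(X, prepend=False, has_constant="add")
    alpha = np.zeros(Xc.shape[1])
    alpha[:-1][penalized_mask] = penalty * len(y)
    model = sm.Logit(y, Xc)
    res = model.fit_regularized(method="l1", alpha=alpha, disp=0,
                                maxiter=500, acc=1e-10, trim_mode="off")
    params = np.asarray(res.params)
    return params[:-1], float(params[-1])


DEFAULT_PENALTY_GRID = (0.0, 3e-4, 1e-3, 3e-3, 1e-2)


def fit_choice_glm(design: DesignMatrix, penalty: float | None = None,
                   cv_folds: int = 10, seed=None, penalize: str = "history",
                   penalty_grid=DEFAULT_PENALTY_GRID) -> HistoryKernelFit:
    """Fit the probabilistic choice model.

    With ``penalty=None`` the lasso penalty is selected from
    ``penalty_grid`` by ``cv_folds``-fold cross-validated deviance (fold
    assignment is deterministic given ``seed``); otherwise the given
    per-observation penalty is used directly.  ``penalize`` chooses which
    coefficients the L1 penalty touches: ``"history"`` (default; intercept
    and contrast weights stay unpenalised) or ``"all"`` (everything except
    the intercept).  Constant history regressors raise an error rather than
    being silently dropped.
    """
    X, y = design.X, design.y
    nc = design.n_contrast
    if penalize == "history":
        penalized_mask = np.zeros(X.shape[1], bool)
        penalized_mask[nc:] = True
    elif penalize == "all":
        penalized_mask = np.ones(X.shape[1], bool)
    else:
        raise ValueError(f"unknown penalize mode {penalize!r}")

    col_sd = X.std(axis=0)
    degenerate = [design.column_names[i] for i in np.where(col_sd == 0)[0]
                  if i >= nc]
    if degenerate:
        raise ValueError(f"degenerate (constant) regressors: {degenerate}")

    cv_dev = None
    if penalty is None:
        if len(y) < cv_folds:
            raise ValueError("fewer analyzable trials than CV folds")
        rng = np.random.default_rng(seed)
        fold = rng.permutation(len(y)) % cv_folds
        cv_dev = {}
        for pen in penalty_grid:
            dev = 0.0
            for f in range(cv_folds):
                tr, te = fold != f, fold == f
                coef, icpt = _fit_at_penalty(X[tr], y[tr], pen, penalized_mask)
                z = np.clip(X[te] @ coef + icpt, -700, 700)
                dev += _deviance(y[te], 1.0 / (1.0 + np.exp(-z)))
            cv_dev[pen] = dev / len(y)
        penalty = min(cv_dev, key=cv_dev.get)

    coef, w0 = _fit_at_penalty(X, y, penalty, penalized_mask)
    nb = design.n_back
    return HistoryKernelFit(
        w_contrast=dict(zip(design.contrast_levels, coef[:nc])),
        w_correct=coef[nc:nc + nb].copy(),
        w_error=coef[nc + nb:nc + 2 * nb].copy(),
        w0=w0, penalty=float(penalty),
        cv_folds=cv_folds if cv_dev else None, cv_deviance=cv_dev)


def simulate_from_kernels(fit: HistoryKernelFit, trials: pd.DataFrame,
                          seed=None) -> pd.DataFrame:
    """Generate choices from known GLM weights on a given stimulus sequence.

    The parameter-recovery forward model: responses are sampled trial by
    trial from the logistic model, so history regressors reflect the
    *simulated* choices and outcomes, exactly as in the recovery analysis.
    """
    rng = np.random.default_rng(seed)
    out = trials.copy().reset_index(drop=True)
    levels = np.asarray(list(fit.w_contrast.keys()), float)
    w_con = np.asarray(list(fit.w_contrast.values()), float)
    nb = len(fit.w_correct)
    choices = np.empty(len(out), dtype="U1")
    outcomes = np.empty(len(out), dtype=np.int8)
    u = rng.random(len(out))
    for _, grp in out.groupby("session_id", sort=False):
        hist_sign: list[float] = []
        hist_outc: list[int] = []
        for row in grp.itertuples():
            i = row.Index
            z = fit.w0 + w_con[np.argmin(np.abs(levels - row.signed_contrast))]
            for n in range(1, min(nb, len(hist_sign)) + 1):
                s, o = hist_sign[-n], hist_outc[-n]
                z += (fit.w_correct[n - 1] if o else fit.w_error[n - 1]) * s
            p_r = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
            ch = "R" if u[i] < p_r else "L"
            oc = 1 if ch == row.side else 0
            choices[i], outcomes[i] = ch, oc
            hist_sign.append(SIDE_SIGN[ch])
            hist_outc.append(oc)
    out["choice"] = choices
    out["outcome"] = outcomes
    return out


def conditioned_psychometric(trials: pd.DataFrame) -> pd.DataFrame:
    """P(right | signed contrast, previous rewarded choice direction).

    Only trials whose previous trial (same session, consecutive index) was
    rewarded enter.  Returns one row per signed contrast with the
    probability of a rightward choice after a previous right or left
    rewarded choice and their difference (right minus left); a positive
    difference indicates a repetition bias.  Empty cells are NaN.
    """
    t = trials.reset_index(drop=True)
    prev_ok = ((t["session_id"] == t["session_id"].shift())
               & (t["trial_index"] == t["trial_index"].shift() + 1)
               & (t["outcome"].shift() == 1)
               & t["choice"].shift().isin(("L", "R"))
               & t["choice"].isin(("L", "R")))
    sub = t[prev_ok].copy()
    sub["prev_choice"] = t["choice"].shift()[prev_ok]
    sub["is_right"] = (sub["choice"] == "R").astype(float)
    table = sub.pivot_table(index="signed_contrast", columns="prev_choice",
                            values="is_right", aggfunc="mean")
    table = table.reindex(columns=["L", "R"])
    table.columns = ["p_right_prev_L", "p_right_prev_R"]
    table["difference"] = table["p_right_prev_R"] - table["p_right_prev_L"]
    return table


def repetition_by_condition(trials: pd.DataFrame, condition: str,
                            max_lag: int = 7, low_contrast: float = 0.0625,
                            high_contrast: float = 1.0,
                            max_run: int = 4) -> pd.DataFrame:
    """Binned model-free repetition probabilities.

    ``condition`` selects the analysis:

    ``"previous_contrast_and_location"``
        4-location task: consecutive-trial pairs with a correct previous
        choice and the same stimulus side; P(repeat previous choice) binned
        by previous contrast (low/high) x same/different altitude, averaged
        over current contrasts.
    ``"nback"``
        P(repeat the n-back choice) for lags 1..``max_lag``, restricted to
        pairs whose n-back trial was correct.
    ``"error_run"``
        P(repeat the previous choice) as a function of the number of
        consecutive errors immediately preceding the current trial
        (1..``max_run``).
    """
    t = trials.reset_index(drop=True)

    if condition == "previous_contrast_and_location":
        if "altitude" not in t.columns:
            raise ValueError("4-location analysis requires an 'altitude' column")
        prev = t.shift()
        pair = ((t["session_id"] == prev["session_id"])
                & (t["trial_index"] == prev["trial_index"] + 1)
                & (prev["outcome"] == 1)
                & (t["side"] == prev["side"]))
        sub = t[pair].copy()
        psub = prev[pair]
        bin_lbl = np.where(np.isclose(psub["contrast"], low_contrast), "low",
                           np.where(np.isclose(psub["contrast"], high_contrast),
                                    "high", "other"))
        sub["prev_contrast_bin"] = bin_lbl
        sub["location"] = np.where(sub["altitude"].to_numpy()
                                   == psub["altitude"].to_numpy(),
                                   "same", "different")
        sub["repeat"] = (sub["choice"].to_numpy()
                         == psub["choice"].to_numpy()).astype(float)
        sub = sub[sub["prev_contrast_bin"] != "other"]
        out = (sub.groupby(["prev_contrast_bin", "location"])["repeat"]
               .agg(["mean", "count"])
               .rename(columns={"mean": "p_repeat", "count": "n"}))
        return out.reset_index()

    if condition == "nback":
        rows = []
        for n in range(1, max_lag + 1):
            back = t.shift(n)
            pair = ((t["session_id"] == back["session_id"])
                    & (t["trial_index"] == back["trial_index"] + n)
                    & (back["outcome"] == 1)
                    & t["choice"].isin(("L", "R")))
            rep = (t["choice"] == back["choice"])[pair]
            rows.append({"lag": n,
                         "p_repeat": rep.mean() if len(rep) else np.nan,
                         "n": int(pair.sum())})
        return pd.DataFrame(rows)

    if condition == "error_run":
        err = (t["outcome"] == 0).to_numpy()
        new_sess = (t["session_id"] != t["session_id"].shift()).to_numpy()
        rep = (t["choice"] == t["choice"].shift()).to_numpy()
        run_before = np.zeros(len(t), int)  # error streak ending at t-1
        streak = 0
        for i in range(len(t)):
            if new_sess[i]:
                streak = 0
            run_before[i] = streak
            streak = streak + 1 if err[i] else 0
        rows = []
        for k in range(1, max_run + 1):
            m = (run_before == k) & ~new_sess
            rows.append({"n_errors": k,
                         "p_repeat": float(rep[m].mean()) if m.any() else np.nan,
                         "n": int(m.sum())})
        return pd.DataFrame(rows)

    raise ValueError(f"unknown condition {condition!r}")
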