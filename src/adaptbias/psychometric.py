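"""Four-parameter psychometric curve and session/trial quality control.

The probability of a rightward choice as a function of signed contrast
``c`` is

``P(R) = gamma + (1 - gamma - lam) * F(c; alpha, beta)``

with ``F(c; alpha, beta) = 1 / (1 + exp(-(c - alpha)/beta))`` a logistic in
contrast, ``gamma``/``lam`` the right/left lapse rates, ``alpha`` the bias
(in contrast units; F crosses 0.5 at ``c = alpha``) and ``beta`` the
contrast threshold (scale).  Sessions are excluded when |bias| > 0.16,
either lapse exceeds 0.2, or accuracy on easy 100 %-contrast trials falls
below 80 %; trials with response times above 12 s are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

#: session exclusion thresholds
MAX_ABS_BIAS = 0.16
MAX_LAPSE = 0.2
MIN_EASY_ACCURACY = 0.8
MAX_RESPONSE_TIME = 12.0


@dataclass
class PsychometricFit:
    """Maximum-likelihood psychometric parameters.

    ``gamma``: right lapse (lower asymptote), ``lam``: left lapse (the
    upper asymptote is ``1 - lam``), ``alpha_bias``: bias in contrast
    units, ``beta``: contrast threshold/scale.
    """

    gamma: float
    lam: float
    alpha_bias: float
    beta: float
    loglik: float
    converged: bool
    message: str = ""

    def predict(self, signed_contrast) -> np.ndarray:
        c = np.asarray(signed_contrast, float)
        z = np.clip((c - self.alpha_bias) / self.beta, -700, 700)
        f = 1.0 / (1.0 + np.exp(-z))
        return self.gamma + (1.0 - self.gamma - self.lam) * f


@dataclass
class ExclusionReport:
    """Per-session QC flags and exclusion counts."""

    flags: pd.DataFrame
    n_sessions_total: int = 0
    n_sessions_excluded: int = 0
    n_trials_total: int = 0
    n_trials_excluded_rt: int = 0


_BOUNDS = [(0.0, 0.5), (0.0, 0.5), (-1.0, 1.0), (1e-3, 2.0)]


def _nll(theta, c, y):
    gamma, lam, a, b = theta
    f = 1.0 / (1.0 + np.exp(-np.clip((c - a) / b, -700, 700)))
    p = np.clip(gamma + (1 - gamma - lam) * f, 1e-9, 1 - 1e-9)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Fit the 4-parameter curve to Bernoulli choices by maximum likelihood.

    Uses bounded L-BFGS-B from a small grid of starting points; raises if
    fewer than two contrast levels carry observations, and reports (rather
    than hides) non-convergence in the returned fit.
    """
    sub = trials[trials["choice"].isin(("L", "R"))]
    c = sub["signed_contrast"].to_numpy(float)
    y = (sub["choice"] == "R").to_numpy(float)
    if len(np.unique(c)) < 2:
        raise ValueError("need observations at >= 2 contrast levels")
    best = None
    for b0 in (0.05, 0.15):
        for l0 in (0.02, 0.15):
            res = minimize(_nll, x0=[l0, l0, 0.0, b0], args=(c, y),
                           method="L-BFGS-B", bounds=_BOUNDS)
            if best is None or res.fun < best.fun:
                best = res
    g, l, a, b = best.x
    return PsychometricFit(gamma=float(g), lam=float(l), alpha_bias=float(a),
                           beta=float(b), loglik=-float(best.fun),
                           converged=bool(best.success),
                           message=str(best.message))


def session_flags(trials: pd.DataFrame, fit: PsychometricFit | None = None) -> dict:
    """QC flags for one session (bias, lapses, easy-trial accuracy)."""
    if fit is None:
        fit = fit_psychometric(trials)
    easy = trials[np.isclose(trials["contrast"], 1.0)]
    easy_acc = easy["outcome"].mean() if len(easy) else np.nan
    return {
        "bias_exceeded": abs(fit.alpha_bias) > MAX_ABS_BIAS,
        "lapse_exceeded": max(fit.gamma, fit.lam) > MAX_LAPSE,
        "easy_accuracy_low": (easy_acc < MIN_EASY_ACCURACY
                              if np.isfinite(easy_acc) else False),
        "easy_accuracy": float(easy_acc) if np.isfinite(easy_acc) else np.nan,
        "gamma": fit.gamma, "lam": fit.lam,
        "alpha_bias": fit.alpha_bias, "beta": fit.beta,
    }


def apply_exclusion(trials: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop disengaged sessions and over-long trials.

    A session is excluded iff any flag is set (|bias| > 0.16, lapse > 0.2,
    or easy-trial accuracy < 80 %); independently, trials with response
    time > 12 s are dropped from the kept sessions.  The operation is
    idempotent.
    """
    rows = []
    excluded_sessions = []
    for sid, grp in trials.groupby("session_id", sort=False):
        flags = session_flags(grp)
        flags["session_id"] = sid
        flags["excluded"] = bool(flags["bias_exceeded"]
                                 or flags["lapse_exceeded"]
                                 or flags["easy_accuracy_low"])
        rows.append(flags)
        if flags["excluded"]:
            excluded_sessions.append(sid)
    flags_df = pd.DataFrame(rows).set_index("session_id")
    kept = trials[~trials["session_id"].isin(excluded_sessions)]
    rt = kept["response_time"]
    slow = rt.notna() & (rt > MAX_RESPONSE_TIME)
    report = ExclusionReport(
        flags=flags_df,
        n_sessions_total=trials["session_id"].nunique(),
        n_sessions_excluded=len(excluded_sessions),
        n_trials_total=len(trials),
        n_trials_excluded_rt=int(slow.sum()),
    )
    return kept[~slow].copy(), report
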