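"""Fit POMDP agents to behavioral summary statistics and compare models.

Agents are fitted not to raw choices but to summary statistics of
behavior: the choice-GLM contrast weights and 7-back correct-choice
kernels of each environment (neutral, repeating, alternating) plus the
correct-choice kernels of neutral sessions split by the preceding day's
regularity (post-repeating, post-alternating).  The cost is the summed
squared difference between empirical and model summary vectors; the model
vector is obtained by simulating the candidate agent on a fixed
interleaved multi-day schedule and running the same GLM pipeline on the
simulated choices.  Common random numbers (a fixed simulation seed across
cost evaluations) make the cost deterministic in the parameters, so a
bound-constrained derivative-free optimizer (Powell) can minimize it from
a grid of starting points.

Nested variants (single inside multi inside extended) are compared with an
F-test on the summary residuals and with BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import f as f_dist

from . import glm
from .agents import PARAM_BOUNDS, AgentParams, make_sessions, simulate_agent

SPLIT_NAMES = ("neutral", "repeating", "alternating", "post_repeating",
               "post_alternating")


@dataclass
class SummaryStatistics:
    """Named blocks of GLM coefficients entering the fitting cost.

    ``components`` maps block names (``contrast_<env>`` and
    ``kernel_<split>``) to coefficient vectors in a fixed order.
    """

    components: dict

    def vector(self) -> np.ndarray:
        return np.concatenate([np.asarray(v, float)
                               for v in self.components.values()])

    @property
    def n_summaries(self) -> int:
        return len(self.vector())


@dataclass
class SimConfig:
    """Simulation protocol used to evaluate the model's summary statistics.

    ``n_days`` sessions of ``trials_per_session`` trials follow the
    interleaved 3-regular/2-neutral schedule drawn once from
    ``schedule_seed``; the first ``burn_in_sessions`` sessions are dropped
    before computing summaries.  ``glm_penalty`` is the fixed lasso penalty
    of the inner GLM fits (0 = unpenalised maximum likelihood, adequate at
    these simulated trial counts and far cheaper than per-evaluation CV).
    """

    n_days: int = 60
    trials_per_session: int = 400
    schedule_seed: int = 20_000
    burn_in_sessions: int = 5
    glm_penalty: float = 0.0
    n_back: int = 7


@dataclass
class FitResult:
    params: AgentParams
    cost: float
    starts: list
    n_summaries: int
    k_params: int


def environment_splits(trials: pd.DataFrame,
                       burn_in_sessions: int = 0) -> dict:
    """Split trials by environment and by post-regularity neutral sessions.

    Returns a dict with the three environments plus ``post_repeating`` /
    ``post_alternating`` (neutral sessions whose preceding session was
    regular).  Sessions with id below ``burn_in_sessions`` are dropped.
    """
    t = trials[trials["session_id"] >= burn_in_sessions]
    env_of = trials.groupby("session_id", sort=True)["environment"].first()
    prev_env = env_of.shift()
    splits = {}
    for env in ("neutral", "repeating", "alternating"):
        splits[env] = t[t["environment"] == env]
    post_rep = env_of.index[(env_of == "neutral") & (prev_env == "repeating")]
    post_alt = env_of.index[(env_of == "neutral") & (prev_env == "alternating")]
    splits["post_repeating"] = t[t["session_id"].isin(post_rep)]
    splits["post_alternating"] = t[t["session_id"].isin(post_alt)]
    return splits


def compute_summary_statistics(trials: pd.DataFrame, penalty: float = 0.0,
                               contrast_levels=None, n_back: int = 7,
                               burn_in_sessions: int = 0,
                               seed=None) -> SummaryStatistics:
    """GLM summary statistics of a behavioral dataset.

    Fits the choice GLM to each environment and to the post-regularity
    neutral splits; collects per-environment contrast weights and the
    correct-choice kernels of all five splits.
    """
    if contrast_levels is None:
        contrast_levels = np.sort(trials["signed_contrast"].unique())
    splits = environment_splits(trials, burn_in_sessions)
    comps = {}
    fits = {}
    for name in SPLIT_NAMES:
        sub = splits[name]
        if len(sub) < 10 * (len(contrast_levels) + 2 * n_back):
            raise ValueError(
                f"split {name!r} has too few trials ({len(sub)}) for a "
                f"stable GLM fit")
        design = glm.build_design_matrix(sub, n_back=n_back,
                                         contrast_levels=contrast_levels)
        fits[name] = glm.fit_choice_glm(design, penalty=penalty, seed=seed)
    for env in ("neutral", "repeating", "alternating"):
        comps[f"contrast_{env}"] = np.asarray(
            list(fits[env].w_contrast.values()))
    for name in SPLIT_NAMES:
        comps[f"kernel_{name}"] = fits[name].w_correct
    return SummaryStatistics(components=comps)


def fitting_schedule(n_days: int):
    """Deterministic balanced interleaved schedule for cost evaluations.

    Cycles blocks of 3 repeating / 2 neutral / 3 alternating / 2 neutral
    days so every environment and both post-regularity neutral splits are
    guaranteed regardless of day count (the behavioral experiment's
    pseudo-randomised block identities, derandomised for common random
    numbers).
    """
    from .task import SessionSchedule, environment
    cycle = (["repeating"] * 3 + ["neutral"] * 2
             + ["alternating"] * 3 + ["neutral"] * 2)
    days = [environment(cycle[i % len(cycle)]) for i in range(n_days)]
    return SessionSchedule(days=days, pattern="interleaved_3_2")


def simulate_summary_statistics(params: AgentParams, sim_config: SimConfig,
                                seed=0) -> SummaryStatistics:
    """Summary statistics of an agent simulated under the fitting protocol."""
    cfg = sim_config
    schedule = fitting_schedule(cfg.n_days)
    sessions = make_sessions(schedule, cfg.trials_per_session,
                             seed=cfg.schedule_seed + 1)
    trials, _ = simulate_agent(params, sessions, seed=seed)
    return compute_summary_statistics(trials, penalty=cfg.glm_penalty,
                                      n_back=cfg.n_back,
                                      burn_in_sessions=cfg.burn_in_sessions)


def compute_summary_cost(params: AgentParams, empirical: SummaryStatistics,
                         sim_config: SimConfig | None = None,
                         seed=0) -> float:
    """Sum of squared differences between empirical and model summaries.

    The model summaries come from a simulation with a fixed seed, so
    repeated evaluations at different parameters share the same random
    numbers and the cost is a deterministic function of ``params``.
    """
    model = simulate_summary_statistics(params, sim_config or SimConfig(),
                                        seed=seed)
    if list(model.components) != list(empirical.components):
        raise ValueError("summary-statistic structures do not match")
    diff = empirical.vector() - model.vector()
    if len(diff) != empirical.n_summaries:
        raise ValueError("summary-statistic lengths do not match")
    return float(np.sum(diff ** 2))


_FREE = {"single": ("sigma", "temperature", "alpha_pos", "alpha_neg"),
         "multi": ("sigma", "temperature", "alpha_pos", "alpha_neg",
                   "memory_strength")}

#: manually-tuned extra starting point (sigma, T, alpha+, alpha-, lambda)
MANUAL_START = dict(sigma=0.14, temperature=0.34, alpha_pos=0.95,
                    alpha_neg=0.95, memory_strength=0.05)


def default_starts(variant: str) -> list[dict]:
    """The fitting start grid: low/high learning rate x weak/strong memory
    (sigma = 0.1, T = 0.3), plus one manually-tuned start."""
    starts = []
    for a in (0.2, 0.8):
        if variant == "multi":
            for lam in (0.05, 0.15):
                starts.append(dict(sigma=0.1, temperature=0.3, alpha_pos=a,
                                   alpha_neg=a, memory_strength=lam))
        else:
            starts.append(dict(sigma=0.1, temperature=0.3, alpha_pos=a,
                               alpha_neg=a))
    manual = {k: MANUAL_START[k] for k in _FREE[variant]}
    starts.append(manual)
    return starts


def _to_params(x, variant):
    kw = dict(zip(_FREE[variant], x))
    if variant == "single":
        kw["memory_strength"] = 0.0
    return AgentParams(variant=variant, **kw)


def fit_agent(empirical: SummaryStatistics, variant: str = "multi",
              starts: list[dict] | None = None,
              sim_config: SimConfig | None = None, seed=0,
              maxfev: int = 200, xtol: float = 1e-3) -> FitResult:
    """Multi-start bounded Powell search over the agent's parameter space.

    Each start is polished with a bound-constrained Powell minimization of
    :func:`compute_summary_cost` (deterministic via common random numbers);
    the best local optimum across starts is returned.  ``maxfev`` caps the
    number of cost evaluations per start.
    """
    if variant not in _FREE:
        raise ValueError("fitting supports the 'single' and 'multi' variants")
    free = _FREE[variant]
    bounds = [PARAM_BOUNDS[name] for name in free]
    if starts is None:
        starts = default_starts(variant)
    sim_config = sim_config or SimConfig()

    def cost_fn(x):
        x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
        return compute_summary_cost(_to_params(x, variant), empirical,
                                    sim_config, seed=seed)

    records = []
    best_x, best_cost = None, np.inf
    for s in starts:
        x0 = np.array([s[name] for name in free])
        res = minimize(cost_fn, x0, method="Powell", bounds=bounds,
                       options=dict(maxfev=maxfev, xtol=xtol, ftol=1e-4))
        records.append({"x0": dict(zip(free, x0)),
                        "x": dict(zip(free, res.x)),
                        "cost": float(res.fun), "nfev": int(res.nfev)})
        if res.fun < best_cost:
            best_cost, best_x = float(res.fun), res.x
    if best_x is None:  # pragma: no cover - defensive
        raise RuntimeError("all optimization starts failed")
    return FitResult(params=_to_params(best_x, variant), cost=best_cost,
                     starts=records, n_summaries=empirical.n_summaries,
                     k_params=len(free))


def compare_models(cost_reduced: float, cost_full: float, n_summaries: int,
                   k_reduced: int, k_full: int) -> dict:
    """Nested-model comparison on summary residual sums of squares.

    ``F = ((RSS_r - RSS_f)/(k_f - k_r)) / (RSS_f/(n - k_f))`` with
    ``n`` the number of summary statistics; ``BIC = n ln(RSS/n) + k ln n``
    and ``delta_bic = BIC_reduced - BIC_full`` (positive favours the full
    model).
    """
    if k_full <= k_reduced:
        raise ValueError("k_full must exceed k_reduced")
    if n_summaries <= k_full:
        raise ValueError("need more summary statistics than parameters")
    df1 = k_full - k_reduced
    df2 = n_summaries - k_full
    F = ((cost_reduced - cost_full) / df1) / (cost_full / df2)
    p = float(f_dist.sf(F, df1, df2))
    bic_r = n_summaries * np.log(cost_reduced / n_summaries) \
        + k_reduced * np.log(n_summaries)
    bic_f = n_summaries * np.log(cost_full / n_summaries) \
        + k_full * np.log(n_summaries)
    return {"F": float(F), "df1": df1, "df2": df2, "p": p,
            "delta_bic": float(bic_r - bic_f)}
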