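"""POMDP reinforcement-learning agents for the visual decision task.

Three nested agent variants perform the two-alternative contrast-detection
task by combining a probabilistic belief about the current stimulus side
with stored values for choice/state pairings:

* **single** — the belief state holds only the current trial's perceptual
  probabilities ``(P_L, P_R)``.  On each trial the agent draws a noisy
  internal contrast estimate ``s_hat ~ N(signed_contrast, sigma**2)``; with a
  flat prior over contrast, the posterior probability that the stimulus was
  on the right is ``P_R = Phi(s_hat / sigma)``.  Expected values are
  ``Q_c = sum_i P_i * q[c, P_i]``; a softmax with temperature ``T`` turns
  them into a choice; the prediction error ``delta = outcome - Q_choice``
  updates the chosen option's values by ``alpha * P_i * delta``, with
  separate learning rates for positive and negative ``delta``.
* **multi** — the belief state additionally carries a memory of the
  previous trial's rewarded choice: ``(M_L, M_R)`` equals ``(lambda, 0)``
  after a rewarded left choice, ``(0, lambda)`` after a rewarded right
  choice and ``(0, 0)`` otherwise.  A second set of memory-choice values
  enters the expected values and is updated with the same learning rate.
  With ``memory_strength = 0`` this reduces exactly to the single variant.
* **extended** — the memory is an exponentially weighted sum over all past
  rewarded choices of each side, ``m = m0 * sum_i exp(-(t - i - 1)/tau)``,
  so both memory activations can be nonzero.

Values persist across sessions (continual learning); memory activations
reset at session boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import EnvironmentSpec, SessionSchedule, generate_stimulus_sequence

_SQRT2 = math.sqrt(2.0)

PARAM_BOUNDS = {
    "sigma": (0.05, 0.5),
    "temperature": (0.01, 1.0),
    "alpha_pos": (0.01, 1.0),
    "alpha_neg": (0.01, 1.0),
    "memory_strength": (0.0, 1.0),
}

#: Best-fitting parameters of the multi-trial agent (pooled mouse data).
BEST_FIT_MULTI = dict(sigma=0.09, alpha_pos=0.96, alpha_neg=0.97,
                      temperature=0.36, memory_strength=0.07)
#: Best-fitting parameters of the single-trial agent.
BEST_FIT_SINGLE = dict(sigma=0.1, alpha_pos=0.41, alpha_neg=1.0,
                       temperature=0.4)


def _phi(x: float) -> float:
    """Standard normal CDF."""
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of a POMDP RL agent.

    ``sigma`` is the sensory-noise standard deviation on the signed-contrast
    scale (the internal contrast estimate is ``s_hat ~ N(s, sigma**2)``),
    ``temperature`` the softmax decision noise, ``alpha_pos``/``alpha_neg``
    the learning rates for positive/negative prediction errors and
    ``memory_strength`` the weight of the previous rewarded choice in the
    belief state (``lambda``; multi variant).  The extended variant replaces
    ``memory_strength`` by an initial strength ``m0`` and a decay constant
    ``tau`` (in trials).
    """

    sigma: float = 0.09
    temperature: float = 0.36
    alpha_pos: float = 0.96
    alpha_neg: float = 0.97
    memory_strength: float = 0.07
    m0: float = 0.07
    tau: float = 1.0
    variant: str = "multi"

    def __post_init__(self):
        if self.variant not in ("single", "multi", "extended"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("sigma", "temperature", "alpha_pos", "alpha_neg"):
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")
        if self.variant == "multi" and not 0.0 <= self.memory_strength <= 1.0:
            raise ValueError("memory_strength must lie in [0, 1]")
        if self.variant == "extended" and self.tau <= 0:
            raise ValueError("tau must be positive")

    @classmethod
    def best_fit(cls, variant: str = "multi") -> "AgentParams":
        if variant == "multi":
            return cls(variant="multi", **BEST_FIT_MULTI)
        if variant == "single":
            return cls(variant="single", memory_strength=0.0, **BEST_FIT_SINGLE)
        raise ValueError("best-fit parameters exist for 'single' and 'multi'")


@dataclass
class BeliefState:
    """Perceptual probabilities plus memory activations for one trial."""

    p_left: float
    p_right: float
    m_left: float = 0.0
    m_right: float = 0.0
    s_hat: float = math.nan


class ValueTable:
    """Stored expected rewards q[choice, state].

    Rows index the choice (0 = L, 1 = R), columns the belief-state component
    in the order ``(P_L, P_R, M_L, M_R)``.  The single-trial agent uses only
    the perceptual block.
    """

    STATES = ("P_L", "P_R", "M_L", "M_R")

    def __init__(self, q=None):
        self.q = np.zeros((2, 4)) if q is None else np.asarray(q, float).copy()
        if self.q.shape != (2, 4):
            raise ValueError("value table must be 2x4 (choice x state)")

    def copy(self) -> "ValueTable":
        return ValueTable(self.q)


def compute_belief(signed_contrast: float, sigma: float, rng=None,
                   s_hat: float | None = None) -> BeliefState:
    """Perceptual belief from a noisy contrast estimate.

    Draws ``s_hat ~ N(signed_contrast, sigma**2)`` (unless an estimate is
    forced) and returns ``P_R = Phi(s_hat / sigma)``, the posterior mass of
    a flat-prior Gaussian belief above zero contrast.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if s_hat is None:
        if rng is None:
            rng = np.random.default_rng()
        s_hat = signed_contrast + sigma * rng.standard_normal()
    p_right = _phi(s_hat / sigma)
    return BeliefState(p_left=1.0 - p_right, p_right=p_right, s_hat=s_hat)


def compute_memory_state(prev_choice: str, prev_outcome: int,
                         memory_strength: float) -> tuple[float, float]:
    """One-back memory activations ``(m_left, m_right)``.

    ``(lambda, 0)`` after a rewarded left choice, ``(0, lambda)`` after a
    rewarded right choice, ``(0, 0)`` otherwise (errors, timeouts, session
    start).
    """
    if not 0.0 <= memory_strength <= 1.0:
        raise ValueError("memory_strength must lie in [0, 1]")
    if prev_outcome == 1 and prev_choice == "L":
        return (memory_strength, 0.0)
    if prev_outcome == 1 and prev_choice == "R":
        return (0.0, memory_strength)
    return (0.0, 0.0)


def compute_extended_memory(rewarded_choice_history, m0: float,
                            tau: float) -> tuple[float, float]:
    """Exponentially decaying memory over all past rewarded choices.

    ``rewarded_choice_history`` lists, oldest first, the choice on each past
    trial of the session as ``"L"``/``"R"`` for rewarded trials and ``None``
    (or anything else) for unrewarded ones.  A choice ``i`` trials before
    the current trial ``t`` contributes weight ``exp(-(t - i - 1)/tau)``,
    i.e. the 1-back trial has weight 1.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = len(rewarded_choice_history)
    m_left = m_right = 0.0
    for i, ch in enumerate(rewarded_choice_history):
        w = math.exp(-(t - i - 1) / tau)
        if ch == "L":
            m_left += w
        elif ch == "R":
            m_right += w
    return (m0 * m_left, m0 * m_right)


def compute_expected_values(belief: BeliefState, values: ValueTable,
                            variant: str = "multi") -> tuple[float, float]:
    """Expected reward of each choice: belief-weighted sums of stored values."""
    q = values.q
    q_l = belief.p_left * q[0, 0] + belief.p_right * q[0, 1]
    q_r = belief.p_left * q[1, 0] + belief.p_right * q[1, 1]
    if variant != "single":
        q_l += belief.m_left * q[0, 2] + belief.m_right * q[0, 3]
        q_r += belief.m_left * q[1, 2] + belief.m_right * q[1, 3]
    return q_l, q_r


def softmax_choice(q_l: float, q_r: float, temperature: float,
                   rng=None) -> tuple[str, float]:
    """Sample a choice from the softmax over the two expected values."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    d = (q_l - q_r) / temperature
    d = min(max(d, -700.0), 700.0)
    p_right = 1.0 / (1.0 + math.exp(d))
    if rng is None:
        rng = np.random.default_rng()
    choice = "R" if rng.random() < p_right else "L"
    return choice, p_right


def update_values(values: ValueTable, belief: BeliefState, choice: str,
                  outcome: int, alpha_pos: float, alpha_neg: float,
                  variant: str = "multi") -> tuple[ValueTable, float]:
    """Prediction-error update of the chosen option's values.

    ``delta = outcome - Q_choice``; each state entry of the chosen row moves
    by ``alpha * activation * delta`` with ``alpha = alpha_pos`` for
    positive and ``alpha_neg`` for negative prediction errors.  Returns a
    new table and the prediction error.
    """
    if choice not in ("L", "R"):
        raise ValueError("choice must be 'L' or 'R'")
    q_l, q_r = compute_expected_values(belief, values, variant)
    q_c = q_l if choice == "L" else q_r
    delta = outcome - q_c
    alpha = alpha_pos if delta > 0 else alpha_neg
    out = values.copy()
    c = 0 if choice == "L" else 1
    out.q[c, 0] += alpha * belief.p_left * delta
    out.q[c, 1] += alpha * belief.p_right * delta
    if variant != "single":
        out.q[c, 2] += alpha * belief.m_left * delta
        out.q[c, 3] += alpha * belief.m_right * delta
    return out, delta


def make_sessions(schedule: SessionSchedule, trials_per_session: int,
                  seed=None) -> list[tuple[EnvironmentSpec, list]]:
    """Generate a stimulus sequence for every day of a schedule."""
    rng = np.random.default_rng(seed)
    sessions = []
    for env in schedule:
        s = int(rng.integers(2**31))
        sessions.append((env, generate_stimulus_sequence(env, trials_per_session, s)))
    return sessions


def simulate_agent(params: AgentParams, sessions, seed=None,
                   values: ValueTable | None = None):
    """Run the full perceive -> value -> choose -> outcome -> update loop.

    Parameters
    ----------
    params:
        Agent parameters; ``params.variant`` selects the model.
    sessions:
        List of ``(environment, sequence)`` pairs, where ``sequence`` is the
        output of :func:`adaptbias.task.generate_stimulus_sequence` (one
        session per day).  Use :func:`make_sessions` to build this from a
        :class:`~adaptbias.task.SessionSchedule`.
    seed:
        Seeds the agent's perceptual and decision noise.  With a shared
        seed and identical sequences, simulations with different parameters
        reuse the same underlying noise draws (common random numbers).
    values:
        Optional initial value table (default all zeros: the agent learns
        the task from scratch).

    Returns
    -------
    (trials, trace):
        Two aligned :class:`pandas.DataFrame` objects.  ``trials`` holds
        one behavioral record per trial; ``trace`` the latent variables,
        including ``Q_pre`` — the choice-probability-weighted expected
        value before the choice — and its perception/memory components.
    """
    variant = params.variant
    sigma = params.sigma
    temp = params.temperature
    a_pos, a_neg = params.alpha_pos, params.alpha_neg
    lam = params.memory_strength
    use_memory = variant != "single"
    extended = variant == "extended"
    if extended:
        m0, decay = params.m0, math.exp(-1.0 / params.tau)

    if values is None:
        values = ValueTable()
    q = values.q.copy()

    n_total = sum(len(seq) for _, seq in sessions)
    rng = np.random.default_rng(seed)
    # Pre-drawn standard normals / uniforms: common random numbers across
    # parameter settings that share the seed and sequences.
    z_all = rng.standard_normal(n_total)
    u_all = rng.random(n_total)

    cols = {name: np.empty(n_total) for name in (
        "p_left", "p_right", "m_left", "m_right", "Q_L", "Q_R",
        "Q_pre", "Q_pre_perception", "Q_pre_memory", "Q_C", "delta",
        "p_right_choice")}
    side_arr = np.empty(n_total, dtype="U1")
    choice_arr = np.empty(n_total, dtype="U1")
    outcome_arr = np.empty(n_total, dtype=np.int8)
    contrast_arr = np.empty(n_total)
    signed_arr = np.empty(n_total)
    session_arr = np.empty(n_total, dtype=np.int32)
    index_arr = np.empty(n_total, dtype=np.int32)
    env_names = []
    alt_arr = np.empty(n_total, dtype=object)
    has_alt = False

    k = 0
    for sess_id, (env, seq) in enumerate(sessions):
        env_name = env.name if isinstance(env, EnvironmentSpec) else str(env)
        env_names.append(env_name)
        prev_choice, prev_outcome = None, 0
        s_l = s_r = 0.0  # extended-memory running sums
        for t, stim in enumerate(seq):
            side, contrast = stim[0], float(stim[1])
            if len(stim) > 2:
                alt_arr[k] = stim[2]
                has_alt = True
            sc = contrast if side == "R" else -contrast

            # perceptual belief
            s_hat = sc + sigma * z_all[k]
            p_r = _phi(s_hat / sigma)
            p_l = 1.0 - p_r

            # memory activations
            if not use_memory:
                m_l = m_r = 0.0
            elif extended:
                m_l, m_r = m0 * s_l, m0 * s_r
            else:
                if prev_outcome == 1 and prev_choice == "L":
                    m_l, m_r = lam, 0.0
                elif prev_outcome == 1 and prev_choice == "R":
                    m_l, m_r = 0.0, lam
                else:
                    m_l = m_r = 0.0

            # expected values
            ql_p = p_l * q[0, 0] + p_r * q[0, 1]
            qr_p = p_l * q[1, 0] + p_r * q[1, 1]
            if use_memory:
                ql_m = m_l * q[0, 2] + m_r * q[0, 3]
                qr_m = m_l * q[1, 2] + m_r * q[1, 3]
            else:
                ql_m = qr_m = 0.0
            q_l_tot, q_r_tot = ql_p + ql_m, qr_p + qr_m

            # softmax choice
            d = (q_l_tot - q_r_tot) / temp
            d = min(max(d, -700.0), 700.0)
            p_rc = 1.0 / (1.0 + math.exp(d))
            choice = "R" if u_all[k] < p_rc else "L"
            outcome = 1 if choice == side else 0

            q_c = q_r_tot if choice == "R" else q_l_tot
            delta = outcome - q_c
            alpha = a_pos if delta > 0 else a_neg
            c = 1 if choice == "R" else 0
            q[c, 0] += alpha * p_l * delta
            q[c, 1] += alpha * p_r * delta
            if use_memory:
                q[c, 2] += alpha * m_l * delta
                q[c, 3] += alpha * m_r * delta

            p_lc = 1.0 - p_rc
            cols["p_left"][k] = p_l
            cols["p_right"][k] = p_r
            cols["m_left"][k] = m_l
            cols["m_right"][k] = m_r
            cols["Q_L"][k] = q_l_tot
            cols["Q_R"][k] = q_r_tot
            cols["Q_pre"][k] = p_lc * q_l_tot + p_rc * q_r_tot
            cols["Q_pre_perception"][k] = p_lc * ql_p + p_rc * qr_p
            cols["Q_pre_memory"][k] = p_lc * ql_m + p_rc * qr_m
            cols["Q_C"][k] = q_c
            cols["delta"][k] = delta
            cols["p_right_choice"][k] = p_rc
            side_arr[k] = side
            choice_arr[k] = choice
            outcome_arr[k] = outcome
            contrast_arr[k] = contrast
            signed_arr[k] = sc
            session_arr[k] = sess_id
            index_arr[k] = t

            if extended:
                s_l = s_l * decay + (1.0 if outcome == 1 and choice == "L" else 0.0)
                s_r = s_r * decay + (1.0 if outcome == 1 and choice == "R" else 0.0)
            prev_choice, prev_outcome = choice, outcome
            k += 1

    env_col = np.repeat(env_names, [len(seq) for _, seq in sessions])
    trials = pd.DataFrame({
        "session_id": session_arr,
        "trial_index": index_arr,
        "environment": env_col,
        "side": side_arr,
        "contrast": contrast_arr,
        "signed_contrast": signed_arr,
        "choice": choice_arr,
        "outcome": outcome_arr,
        "response_time": np.nan,
    })
    if has_alt:
        trials["altitude"] = alt_arr
    trace = pd.DataFrame({"session_id": session_arr, "trial_index": index_arr,
                          **cols})
    values.q = q
    return trials, trace
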