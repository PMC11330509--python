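"""2-state GLM-HMM for labelling engaged and disengaged trials.

Each hidden state carries a Bernoulli GLM of choice on the stimulus:
``P(right | state s) = sigmoid(w_s[0] * signed_contrast + w_s[1])`` — a
stimulus slope plus a stimulus-independent bias.  The engaged state has a
large stimulus slope (choices track the stimulus), the disengaged state a
slope near zero (choices ignore the stimulus).  States evolve as a Markov
chain across trials within a session; sessions are independent sequences.

The model is fitted by EM (Baum-Welch): the E-step runs scaled
forward-backward over the two states, the M-step re-estimates the
transition matrix from expected transition counts and each state's GLM by
posterior-weighted logistic regression.  Maximum-likelihood transitions,
no priors.  The best of ``n_init`` random initialisations is kept, and
states are canonically ordered by stimulus slope (state 0 = engaged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression


@dataclass
class GlmHmmFit:
    """Fitted GLM-HMM: emissions, dynamics and per-trial posteriors."""

    weights: np.ndarray          # (n_states, 2): [stimulus slope, bias]
    transmat: np.ndarray         # (n_states, n_states), rows sum to 1
    init_probs: np.ndarray       # (n_states,)
    posteriors: np.ndarray       # (n_trials, n_states), smoothed
    loglik_trace: list
    converged: bool
    n_states: int = 2

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _design(trials: pd.DataFrame):
    X = np.column_stack([trials["signed_contrast"].to_numpy(float),
                         np.ones(len(trials))])
    y = (trials["choice"].to_numpy() == "R").astype(float)
    return X, y


def _emission_probs(weights, X, y):
    """b[t, s] = P(y_t | state s)."""
    z = np.clip(X @ weights.T, -700, 700)
    p = 1.0 / (1.0 + np.exp(-z))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.where(y[:, None] == 1, p, 1 - p)


def _session_bounds(trials):
    sizes = trials.groupby("session_id", sort=False).size().to_numpy()
    ends = np.cumsum(sizes)
    return np.column_stack([ends - sizes, ends])


def forward_backward(b, transmat, init_probs):
    """Scaled forward-backward for one sequence of emission likelihoods.

    Returns (gamma, xi_sum, loglik): smoothed posteriors, summed expected
    transition counts, and the sequence log-likelihood.
    """
    T, S = b.shape
    alpha = np.empty((T, S))
    c = np.empty(T)
    alpha[0] = init_probs * b[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ transmat) * b[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, S))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transmat @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((S, S))
    for t in range(T - 1):
        xi = (alpha[t][:, None] * transmat * (b[t + 1] * beta[t + 1])[None, :]
              / c[t + 1])
        xi_sum += xi
    return gamma, xi_sum, float(np.log(c).sum())


def sequence_loglik(weights, transmat, init_probs, trials: pd.DataFrame) -> float:
    """Log-likelihood of a trial table under fixed GLM-HMM parameters."""
    X, y = _design(trials)
    b = _emission_probs(np.asarray(weights, float), X, y)
    total = 0.0
    for s0, s1 in _session_bounds(trials):
        _, _, ll = forward_backward(b[s0:s1], np.asarray(transmat, float),
                                    np.asarray(init_probs, float))
        total += ll
    return total


def _m_step_weights(X, y, gamma, old_weights):
    S = gamma.shape[1]
    W = np.empty_like(old_weights)
    for s in range(S):
        w_obs = gamma[:, s]
        if w_obs.sum() < 1e-6 or len(np.unique(y)) < 2:
            W[s] = old_weights[s]
            continue
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500,
                                 tol=1e-8, fit_intercept=False)
        clf.fit(X, y, sample_weight=w_obs)
        W[s] = clf.coef_[0]
    return W


def fit_glm_hmm(trials: pd.DataFrame, n_states: int = 2, n_init: int = 5,
                max_iter: int = 100, tol: float = 1e-5,
                seed=None) -> GlmHmmFit:
    """Fit the GLM-HMM by EM from several random initialisations.

    The trial table needs ``session_id``, ``signed_contrast`` and binary
    ``choice``.  The per-iteration log-likelihood is recorded and is
    non-decreasing up to the M-step solver tolerance; non-convergence
    after ``max_iter`` iterations returns the best iterate with a warning.
    """
    X, y = _design(trials)
    bounds = _session_bounds(trials)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_init):
        weights = np.column_stack([rng.normal(2.0, 2.0, n_states),
                                   rng.normal(0.0, 0.5, n_states)])
        transmat = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(transmat, 0.9)
        transmat += rng.uniform(0, 0.05, transmat.shape)
        transmat /= transmat.sum(axis=1, keepdims=True)
        init_probs = np.full(n_states, 1.0 / n_states)

        trace = []
        converged = False
        gamma_all = np.empty((len(y), n_states))
        for _it in range(max_iter):
            b = _emission_probs(weights, X, y)
            ll = 0.0
            xi_total = np.zeros((n_states, n_states))
            init_acc = np.zeros(n_states)
            for s0, s1 in bounds:
                gamma, xi, ll_seq = forward_backward(b[s0:s1], transmat,
                                                     init_probs)
                gamma_all[s0:s1] = gamma
                xi_total += xi
                init_acc += gamma[0]
                ll += ll_seq
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
            transmat = xi_total / np.clip(xi_total.sum(axis=1, keepdims=True),
                                          1e-12, None)
            init_probs = init_acc / init_acc.sum()
            weights = _m_step_weights(X, y, gamma_all, weights)
        if not converged:
            warnings.warn("GLM-HMM EM did not converge within "
                          f"{max_iter} iterations; returning best iterate")
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], weights, transmat, init_probs,
                    gamma_all.copy(), trace, converged)

    ll, weights, transmat, init_probs, gamma_all, trace, converged = best
    order = np.argsort(-weights[:, 0])  # state 0 = engaged (largest slope)
    weights = weights[order]
    transmat = transmat[np.ix_(order, order)]
    init_probs = init_probs[order]
    gamma_all = gamma_all[:, order]
    return GlmHmmFit(weights=weights, transmat=transmat,
                     init_probs=init_probs, posteriors=gamma_all,
                     loglik_trace=trace, converged=converged,
                     n_states=n_states)


def decode_states(fit: GlmHmmFit, trials: pd.DataFrame,
                  method: str = "smoothed"):
    """Per-trial engagement labels and posteriors for a trial table.

    ``"smoothed"`` labels each trial by the maximum of its smoothed
    (forward-backward) posterior; ``"viterbi"`` returns the jointly most
    probable state path.  Posteriors sum to one per trial in either case.
    """
    X, y = _design(trials)
    b = _emission_probs(fit.weights, X, y)
    bounds = _session_bounds(trials)
    post = np.empty((len(y), fit.n_states))
    labels = np.empty(len(y), dtype=int)
    for s0, s1 in bounds:
        gamma, _, _ = forward_backward(b[s0:s1], fit.transmat, fit.init_probs)
        post[s0:s1] = gamma
        if method == "smoothed":
            labels[s0:s1] = gamma.argmax(axis=1)
        elif method == "viterbi":
            labels[s0:s1] = _viterbi(b[s0:s1], fit.transmat, fit.init_probs)
        else:
            raise ValueError(f"unknown decoding method {method!r}")
    return labels, post


def _viterbi(b, transmat, init_probs):
    T, S = b.shape
    logb = np.log(b)
    logA = np.log(np.clip(transmat, 1e-300, None))
    delta = np.log(np.clip(init_probs, 1e-300, None)) + logb[0]
    back = np.zeros((T, S), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = delta.argmax()
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path
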