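"""Fiber-photometry preprocessing and value-related dopamine analyses.

Two excitation wavelengths are acquired on alternating frames (40 Hz): a
dopamine-sensitive 470 nm signal and a 415 nm isosbestic control that
shares motion and photobleaching artifacts but carries no dopamine
transients.  Preprocessing regresses the control onto the signal
(least-squares ``a + b * control``) and forms

``dF/F = (signal_470 - fitted_control) / fitted_control``

then high-pass filters by subtracting a 25 s moving average and z-scores
the session trace.  Event-aligned windows of the z-scored trace,
baselined to the pre-stimulus period, yield per-trial scalar dopamine
responses (mean over the stimulus window, truncated at each trial's
outcome time).

The history analysis compares per-trial values between trials whose
stimulus side *repeats* versus *alternates* the n-back trial's side,
restricted to pairs in which both trials were rewarded.  Applied to the
agent's expected value this difference is called dQ; applied to measured
dopamine it is dDA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PhotometrySession:
    """De-interleaved two-channel photometry plus task events.

    Each channel has its own time base (seconds); events are stimulus
    onsets and outcome times with a rewarded flag per trial.
    """

    time_470: np.ndarray
    signal_470: np.ndarray
    time_415: np.ndarray
    control_415: np.ndarray
    stim_onsets: np.ndarray
    outcome_times: np.ndarray
    rewarded: np.ndarray
    fs: float = 20.0

    def common_grid(self):
        """Interpolate both channels onto the 470-channel time base."""
        ctrl = np.interp(self.time_470, self.time_415, self.control_415)
        return self.time_470, self.signal_470, ctrl


def compute_dff(signal_470, control_415, fs: float = 20.0,
                highpass_window: float = 25.0, zscore: bool = True):
    """Isosbestic-corrected, high-passed, z-scored dF/F trace.

    Fits ``a + b * control`` to the signal by least squares, computes
    ``(signal - fitted) / fitted``, subtracts a centred moving average of
    ``highpass_window`` seconds (shrinking at the edges) and z-scores.
    Raises on unequal lengths or a constant control trace.
    """
    s = np.asarray(signal_470, float)
    c = np.asarray(control_415, float)
    if s.shape != c.shape:
        raise ValueError("signal and control must have equal length")
    if np.ptp(c) == 0:
        raise ValueError("constant control trace: isosbestic regression "
                         "is degenerate")
    b, a = np.polyfit(c, s, 1)
    fitted = a + b * c
    if np.any(fitted <= 0):
        raise ValueError("fitted control is not positive everywhere; "
                         "dF/F undefined")
    dff = (s - fitted) / fitted
    if highpass_window:
        w = max(int(round(highpass_window * fs)), 1)
        baseline = (pd.Series(dff).rolling(w, center=True, min_periods=1)
                    .mean().to_numpy())
        dff = dff - baseline
    if zscore:
        sd = dff.std()
        if sd > 0:
            dff = (dff - dff.mean()) / sd
    return dff


def align_events(trace, event_times, fs: float = 20.0, t0: float = 0.0,
                 window: tuple = (-1.0, 2.0),
                 baseline_window: tuple = (-0.5, 0.0),
                 baseline_mode: str = "current"):
    """Extract per-event windows from a trace, with pre-event baselining.

    ``baseline_mode`` is ``"current"`` (subtract the event's own
    pre-stimulus mean), ``"previous"`` (subtract the *previous* event's
    pre-stimulus mean — the carryover control, which leaves the current
    pre-stimulus samples free to differ from zero) or ``"none"``.
    Events whose window exceeds the trace span are dropped and counted.

    Returns ``(matrix, lags, kept, n_dropped)``: the trial x time matrix,
    the lag (s) of each column relative to the event, the indices of the
    events kept, and the number dropped at the edges.
    """
    trace = np.asarray(trace, float)
    event_times = np.asarray(event_times, float)
    lo = int(np.floor(window[0] * fs))
    hi = int(np.ceil(window[1] * fs))
    lags = np.arange(lo, hi + 1) / fs
    b_lo = int(np.floor(baseline_window[0] * fs))
    b_hi = int(np.floor(baseline_window[1] * fs))
    centers = np.round((event_times - t0) * fs).astype(int)
    ok = ((centers + min(lo, b_lo) >= 0)
          & (centers + max(hi, b_hi) < len(trace)))
    if baseline_mode == "previous":
        prev_ok = np.roll(ok, 1)
        prev_ok[0] = False
        ok = ok & prev_ok
    kept = np.where(ok)[0]
    mat = np.empty((len(kept), len(lags)))
    for row, i in enumerate(kept):
        seg = trace[centers[i] + lo: centers[i] + hi + 1]
        if baseline_mode == "current":
            base_center = centers[i]
        elif baseline_mode == "previous":
            base_center = centers[i - 1]
        elif baseline_mode == "none":
            base_center = None
        else:
            raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
        if base_center is None:
            base = 0.0
        else:
            base = trace[base_center + b_lo: base_center + b_hi].mean()
        mat[row] = seg - base
    return mat, lags, kept, int(len(event_times) - len(kept))


def stimulus_response(aligned: np.ndarray, lags: np.ndarray,
                      stim_times, outcome_times,
                      window: tuple = (0.0, 0.6)) -> np.ndarray:
    """Per-trial scalar dopamine: mean over the stimulus window.

    The window is ``window`` seconds after stimulus onset, truncated at
    each trial's outcome time so reward-related samples never enter.
    Trials whose outcome precedes the stimulus raise; trials whose outcome
    arrives before the first window sample yield NaN.
    """
    stim_times = np.asarray(stim_times, float)
    outcome_times = np.asarray(outcome_times, float)
    if len(stim_times) != len(aligned):
        raise ValueError("one stimulus/outcome time pair per aligned row")
    latency = outcome_times - stim_times
    if np.any(latency < 0):
        raise ValueError("outcome precedes stimulus on some trials")
    out = np.full(len(aligned), np.nan)
    in_window = (lags >= window[0]) & (lags < window[1])
    for i in range(len(aligned)):
        use = in_window & (lags < latency[i])
        if use.any():
            out[i] = aligned[i, use].mean()
    return out


def delta_curve(values, trials: pd.DataFrame, max_lag: int = 7) -> pd.DataFrame:
    """Repetition-minus-alternation difference of a per-trial value by lag.

    For each lag ``n`` the difference is the mean value over trials whose
    stimulus side equals the n-back trial's side minus the mean over
    trials whose side differs, restricted to pairs in which both the
    current and the n-back trial were rewarded (and lie in the same
    session, exactly ``n`` indices apart).  Empty cells yield NaN with
    count 0.  Computed on agent values this is dQ; on dopamine scalars,
    dDA.
    """
    t = trials.reset_index(drop=True)
    v = np.asarray(values, float)
    if len(v) != len(t):
        raise ValueError("values must align with the trial table")
    rows = []
    for n in range(1, max_lag + 1):
        back = t.shift(n)
        valid = ((t["session_id"] == back["session_id"])
                 & (t["trial_index"] == back["trial_index"] + n)
                 & (t["outcome"] == 1) & (back["outcome"] == 1)
                 & np.isfinite(v))
        rep = (t["side"] == back["side"]) & valid
        alt = (t["side"] != back["side"]) & valid
        m_rep = v[rep.to_numpy()].mean() if rep.any() else np.nan
        m_alt = v[alt.to_numpy()].mean() if alt.any() else np.nan
        rows.append({"lag": n, "delta": m_rep - m_alt,
                     "mean_repeat": m_rep, "mean_alternate": m_alt,
                     "n_repeat": int(rep.sum()), "n_alternate": int(alt.sum())})
    return pd.DataFrame(rows)


def q_components(trace: pd.DataFrame, memory_weight: float = 1.0) -> np.ndarray:
    """Reweight the memory contribution of the pre-choice expected value.

    Returns ``Q_pre_perception + memory_weight * Q_pre_memory`` per trial;
    ``memory_weight = 1`` reproduces ``Q_pre``, 0 the perception-only
    expectation, and large weights a memory-dominated expectation.  Raises
    for traces without a memory contribution (single-trial agent).
    """
    for col in ("Q_pre_perception", "Q_pre_memory"):
        if col not in trace.columns:
            raise ValueError(f"trace lacks column {col!r}")
    mem = trace["Q_pre_memory"].to_numpy(float)
    if np.allclose(mem, 0.0):
        raise ValueError("trace has no memory component "
                         "(single-trial agent or memory_strength = 0)")
    return trace["Q_pre_perception"].to_numpy(float) + memory_weight * mem
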