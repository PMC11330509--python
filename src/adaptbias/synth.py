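"""One-stop synthetic data generator: behavior plus coupled photometry.

The generator composes the task environments and the POMDP agents into
complete multi-day behavioral datasets, and renders the agent's latent
variables into realistic two-channel photometry: the 470 nm channel
carries photobleaching, a motion artifact shared with the 415 nm
isosbestic channel, white noise, and dopamine transients whose amplitude
scales with the agent's pre-choice expected value ``Q_pre`` at stimulus
onset and with the prediction error ``delta`` at outcome; the isosbestic
channel carries everything except the transients.

Event timing mimics the recording sessions: a wheel-quiescence re-arm
delay and a 0.7-0.8 s hold precede each stimulus; the response arrives
after a lognormal response time (median 0.5 s, truncated at 12 s); the
inter-trial interval is uniform between 1 and 3 s.  With the defaults the
median inter-stimulus interval is ~5.55 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import AgentParams, make_sessions, simulate_agent
from .photometry import PhotometrySession
from .task import generate_session_schedule


@dataclass
class GeneratorConfig:
    """Defaults reproduce the study conditions.

    Behavioral defaults: interleaved 3-regular/2-neutral schedule, ~400
    trials per session, the best-fitting multi-trial agent.  Timing (s):
    ITI uniform 1-3, hold uniform 0.7-0.8, lognormal response times with
    median 0.5 truncated at 12, and a lognormal re-arm delay (the wait for
    the wheel to be still) calibrated so the median inter-stimulus
    interval is ~5.55.  Photometry: GRAB-DA-like kinetics (50 ms rise,
    1 s decay), slow photobleaching, a shared motion artifact and white
    noise per channel.
    """

    # behavior
    n_days: int = 20
    trials_per_session: int = 400
    pattern: str = "interleaved_3_2"
    params: AgentParams = field(default_factory=AgentParams.best_fit)
    seed: int = 0
    # event timing (seconds)
    iti_range: tuple = (1.0, 3.0)
    hold_range: tuple = (0.7, 0.8)
    rt_median: float = 0.5
    rt_sigma: float = 0.7
    rt_max: float = 12.0
    rearm_median: float = 2.1
    rearm_sigma: float = 0.5
    # photometry
    fs_channel: float = 20.0
    rise: float = 0.05
    decay: float = 1.0
    bleach_tau: float = 1200.0
    bleach_floor: float = 0.6
    base_470: float = 100.0
    base_415: float = 80.0
    artifact_sd: float = 1.0
    artifact_smooth: float = 0.5
    noise_sd: float = 0.3
    stim_gain: float = 4.0
    outcome_gain: float = 4.0


def _lognormal(rng, median, sigma, size):
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=size)


def generate_behavior_dataset(config: GeneratorConfig):
    """Schedule -> stimulus sequences -> agent simulation -> trial table.

    Returns ``(trials, trace)``; ``trials`` includes response times drawn
    from the timing model, and the agent's value table persists across
    days (continual learning).  Byte-identical output for a fixed seed.
    """
    ss = np.random.SeedSequence(config.seed)
    s_sched, s_seq, s_agent, s_rt = [int(s.generate_state(1)[0] % 2**31)
                                     for s in ss.spawn(4)]
    schedule = generate_session_schedule(config.n_days, config.pattern,
                                         seed=s_sched)
    sessions = make_sessions(schedule, config.trials_per_session, seed=s_seq)
    trials, trace = simulate_agent(config.params, sessions, seed=s_agent)
    rng = np.random.default_rng(s_rt)
    rt = _lognormal(rng, config.rt_median, config.rt_sigma, len(trials))
    rt = np.minimum(rt, config.rt_max)
    trials["response_time"] = rt
    return trials, trace


def generate_event_times(trials: pd.DataFrame, config: GeneratorConfig,
                         rng=None):
    """Stimulus-onset and outcome times for one continuous recording.

    Each trial contributes re-arm + hold before the stimulus, the trial's
    response time to the outcome, and an ITI after it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(trials)
    rearm = _lognormal(rng, config.rearm_median, config.rearm_sigma, n)
    hold = rng.uniform(*config.hold_range, n)
    iti = rng.uniform(*config.iti_range, n)
    rt = trials["response_time"].to_numpy(float)
    if np.isnan(rt).any():
        raise ValueError("trials need response times; use "
                         "generate_behavior_dataset or fill response_time")
    stim = np.empty(n)
    outcome = np.empty(n)
    t = 5.0  # lead-in
    for i in range(n):
        t += rearm[i] + hold[i]
        stim[i] = t
        t += rt[i]
        outcome[i] = t
        t += iti[i]
    return stim, outcome


def _transient_kernel(config: GeneratorConfig):
    t = np.arange(0, 5 * config.decay, 1.0 / config.fs_channel)
    k = (1.0 - np.exp(-t / config.rise)) * np.exp(-t / config.decay)
    peak = k.max()
    return k / peak if peak > 0 else k


def _smooth(x, sd_samples):
    if sd_samples <= 0:
        return x
    w = int(6 * sd_samples) | 1
    g = np.exp(-0.5 * ((np.arange(w) - w // 2) / sd_samples) ** 2)
    g /= g.sum()
    return np.convolve(x, g, mode="same")


def generate_photometry_dataset(trace: pd.DataFrame, trials: pd.DataFrame,
                                config: GeneratorConfig) -> PhotometrySession:
    """Render agent latents into a two-channel photometry recording.

    The 470 nm channel is ``bleach + shared artifact + transients +
    noise`` with stimulus-locked transient amplitude ``stim_gain * Q_pre``
    and outcome-locked amplitude ``outcome_gain * delta``; the 415 nm
    channel lacks the transients.  Channels are sampled on 20 Hz grids
    offset by half a frame, mimicking de-interleaved 40 Hz acquisition.
    """
    if len(trace) != len(trials):
        raise ValueError("trace and trials must have equal length")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + 7))
    stim, outcome = generate_event_times(trials, config, rng)
    fs = config.fs_channel
    duration = outcome[-1] + 10.0
    t470 = np.arange(0.0, duration, 1.0 / fs)
    t415 = t470 + 0.5 / fs

    n = len(t470)
    impulses = np.zeros(n)
    q = trace["Q_pre"].to_numpy(float)
    d = trace["delta"].to_numpy(float)
    idx_stim = np.round(stim * fs).astype(int)
    idx_out = np.round(outcome * fs).astype(int)
    np.add.at(impulses, idx_stim, config.stim_gain * q)
    np.add.at(impulses, idx_out, config.outcome_gain * d)
    transients = np.convolve(impulses, _transient_kernel(config))[:n]

    artifact = _smooth(rng.normal(0.0, 1.0, n),
                       config.artifact_smooth * fs) * config.artifact_sd
    # same artifact realisation on the offset grid, scaled with channel
    # brightness so the isosbestic regression can remove it
    artifact_415 = np.interp(t415, t470, artifact) \
        * (config.base_415 / config.base_470)

    def bleach(t, base):
        f = config.bleach_floor
        return base * (f + (1 - f) * np.exp(-t / config.bleach_tau))

    # transient amplitude scales with the surviving fluorophore pool, so
    # dF/F has a stable gain across the session despite photobleaching
    b470 = bleach(t470, config.base_470)
    sig470 = (b470 + artifact + transients * (b470 / config.base_470)
              + rng.normal(0.0, config.noise_sd, n))
    ctl415 = (bleach(t415, config.base_415) + artifact_415
              + rng.normal(0.0, config.noise_sd, n))
    return PhotometrySession(time_470=t470, signal_470=sig470,
                             time_415=t415, control_415=ctl415,
                             stim_onsets=stim, outcome_times=outcome,
                             rewarded=trials["outcome"].to_numpy(), fs=fs)
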