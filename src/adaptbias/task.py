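"""Stimulus sequences and session schedules with controlled temporal regularities.

The task presents a grating of variable contrast on the left or right side
of a screen.  The side sequence is a first-order Markov chain: each stimulus
repeats the previous trial's side with probability ``p_repeat``.  Three named
environments are used throughout: *neutral* (p_repeat = 0.5, i.i.d. sides),
*repeating* (0.8) and *alternating* (0.2).  Sessions are run on different
days; the study's schedule interleaves blocks of three regular (repeating or
alternating) days with two neutral days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Unsigned contrast fractions used in the full task (100 .. 0 %).
DEFAULT_CONTRAST_LEVELS = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.0)

PRESET_P_REPEAT = {"neutral": 0.5, "repeating": 0.8, "alternating": 0.2}


@dataclass(frozen=True)
class EnvironmentSpec:
    """A stimulus environment: transition statistics plus contrast set.

    Parameters
    ----------
    name:
        ``"neutral"``, ``"repeating"``, ``"alternating"`` or ``"custom"``.
        For the named presets ``p_repeat`` must equal 0.5 / 0.8 / 0.2.
    p_repeat:
        Probability that the stimulus side repeats the previous trial's side.
    contrast_levels:
        Unsigned contrast fractions in [0, 1].
    contrast_weights:
        Sampling distribution over ``contrast_levels`` (default uniform).
    vertical_locations:
        Optional altitudes for the 4-location task variant, e.g.
        ``("low", "high")``; ``None`` for the standard 2-location task.
    """

    name: str = "neutral"
    p_repeat: float = 0.5
    contrast_levels: tuple = DEFAULT_CONTRAST_LEVELS
    contrast_weights: tuple | None = None
    vertical_locations: tuple | None = None

    def __post_init__(self):
        if not 0.0 < self.p_repeat < 1.0:
            raise ValueError(f"p_repeat must lie in (0, 1), got {self.p_repeat}")
        preset = PRESET_P_REPEAT.get(self.name)
        if preset is not None and abs(self.p_repeat - preset) > 1e-12:
            raise ValueError(
                f"environment {self.name!r} requires p_repeat={preset}, "
                f"got {self.p_repeat}"
            )
        if preset is None and self.name != "custom":
            raise ValueError(f"unknown environment name {self.name!r}")
        if self.contrast_weights is not None:
            w = np.asarray(self.contrast_weights, float)
            if len(w) != len(self.contrast_levels):
                raise ValueError("contrast_weights length mismatch")
            if abs(w.sum() - 1.0) > 1e-8 or (w < 0).any():
                raise ValueError("contrast_weights must be a distribution")

    @property
    def weights(self) -> np.ndarray:
        if self.contrast_weights is None:
            n = len(self.contrast_levels)
            return np.full(n, 1.0 / n)
        return np.asarray(self.contrast_weights, float)


def environment(name: str, **kwargs) -> EnvironmentSpec:
    """Build a preset environment by name (neutral / repeating / alternating)."""
    return EnvironmentSpec(name=name, p_repeat=PRESET_P_REPEAT[name], **kwargs)


@dataclass
class SessionSchedule:
    """Ordered multi-day schedule: one :class:`EnvironmentSpec` per day."""

    days: list[EnvironmentSpec] = field(default_factory=list)
    pattern: str = "interleaved_3_2"

    def __len__(self):
        return len(self.days)

    def __iter__(self):
        return iter(self.days)


def generate_stimulus_sequence(
    env: EnvironmentSpec, n_trials: int, seed=None
) -> list[tuple]:
    """Draw a stimulus sequence from a first-order Markov side process.

    The first side is uniform; each subsequent side repeats the previous one
    with probability ``env.p_repeat``.  Contrasts are i.i.d. from the
    environment's contrast distribution; altitudes (if configured) are
    uniform and independent.

    Returns a list of ``(side, contrast)`` tuples — ``(side, contrast,
    altitude)`` when ``env.vertical_locations`` is set — with sides in
    ``{"L", "R"}``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    repeat = rng.random(n_trials) < env.p_repeat
    sides = np.empty(n_trials, dtype=np.int8)
    sides[0] = rng.integers(2)
    for i in range(1, n_trials):
        sides[i] = sides[i - 1] if repeat[i] else 1 - sides[i - 1]
    contrasts = rng.choice(np.asarray(env.contrast_levels, float),
                           size=n_trials, p=env.weights)
    side_labels = np.array(["L", "R"])
    if env.vertical_locations is None:
        return list(zip(side_labels[sides], contrasts))
    alts = rng.choice(np.asarray(env.vertical_locations, object), size=n_trials)
    return list(zip(side_labels[sides], contrasts, alts))


def generate_session_schedule(
    n_days: int,
    pattern: str = "interleaved_3_2",
    seed=None,
    env_kwargs: dict | None = None,
) -> SessionSchedule:
    """Lay out environments over days.

    ``interleaved_3_2`` emits blocks of three regular days (repeating or
    alternating, identity pseudo-randomised per block) followed by two
    neutral days, as in the main experiment.  ``random`` draws environments
    i.i.d. uniformly from the three presets; ``neutral_only`` emits neutral
    days throughout (the dopamine-recording protocol).
    """
    if pattern not in ("interleaved_3_2", "random", "neutral_only"):
        raise ValueError(f"unknown schedule pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    env_kwargs = env_kwargs or {}
    days: list[EnvironmentSpec] = []
    if pattern == "neutral_only":
        days = [environment("neutral", **env_kwargs) for _ in range(n_days)]
    elif pattern == "random":
        names = rng.choice(["neutral", "repeating", "alternating"], size=n_days)
        days = [environment(n, **env_kwargs) for n in names]
    else:
        while len(days) < n_days:
            regular = "repeating" if rng.integers(2) else "alternating"
            days.extend(environment(regular, **env_kwargs) for _ in range(3))
            days.extend(environment("neutral", **env_kwargs) for _ in range(2))
        days = days[:n_days]
    return SessionSchedule(days=days, pattern=pattern)


def repeat_frequency(sides) -> float:
    """Empirical fraction of trials whose side repeats the previous side."""
    s = np.asarray(sides)
    if len(s) < 2:
        raise ValueError("need at least two trials")
    return float(np.mean(s[1:] == s[:-1]))
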