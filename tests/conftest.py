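"""Shared simulation fixtures.

The heavyweight simulations (multi-day agent runs) are session-scoped so
that signature tests and acceptance tests reuse the same datasets.
"""

import numpy as np
import pytest

from adaptbias import agents, task


@pytest.fixture(scope="session")
def neutral_sessions():
    """150 neutral days x 400 trials of stimulus sequences."""
    sched = task.SessionSchedule([task.environment("neutral")] * 150,
                                 pattern="custom")
    return agents.make_sessions(sched, 400, seed=210)


@pytest.fixture(scope="session")
def multi_neutral(neutral_sessions):
    """Best-fit multi-trial agent on the neutral sessions."""
    params = agents.AgentParams.best_fit("multi")
    return agents.simulate_agent(params, neutral_sessions, seed=211)


@pytest.fixture(scope="session")
def single_neutral():
    """Best-fit single-trial agent on a long neutral-only dataset.

    The single-trial agent's lag-1-vs-lag-2 contrasts are an order of
    magnitude smaller than the multi-trial agent's, so its signature
    checks need a longer simulation to clear Monte-Carlo error.
    """
    from adaptbias import synth
    cfg = synth.GeneratorConfig(
        n_days=400, trials_per_session=400, pattern="neutral_only",
        params=agents.AgentParams.best_fit("single"), seed=400)
    return synth.generate_behavior_dataset(cfg)


@pytest.fixture(scope="session")
def interleaved_schedule():
    sched = task.generate_session_schedule(100, "interleaved_3_2", seed=310)
    return agents.make_sessions(sched, 400, seed=311)


@pytest.fixture(scope="session")
def multi_interleaved(interleaved_schedule):
    """Best-fit multi-trial agent on a 100-day interleaved schedule."""
    params = agents.AgentParams.best_fit("multi")
    return agents.simulate_agent(params, interleaved_schedule, seed=312)


@pytest.fixture(scope="session")
def single_interleaved(interleaved_schedule):
    params = agents.AgentParams.best_fit("single")
    return agents.simulate_agent(params, interleaved_schedule, seed=312)
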