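"""Recover agent parameters from behavioral summary statistics.

Simulates the multi-trial agent at its best-fit parameters, computes the
summary statistics the fitting procedure targets (per-environment
contrast weights and correct-choice kernels plus the post-regularity
neutral kernels), and re-fits the agent from the manual starting point
with a small optimisation budget.  The recovered sensory noise and
memory strength should approach the generating values (sigma = 0.09,
lambda = 0.07); learning rates are less tightly constrained by these
summaries.  A production fit uses the full 9-start grid and a larger
evaluation budget.
"""

from adaptbias import agents, task
from adaptbias.fitting import (MANUAL_START, SimConfig,
                               compute_summary_statistics, fit_agent)

truth = agents.AgentParams.best_fit("multi")
schedule = task.generate_session_schedule(120, "interleaved_3_2", seed=21)
sessions = agents.make_sessions(schedule, 400, seed=22)
trials, _ = agents.simulate_agent(truth, sessions, seed=23)
summaries = compute_summary_statistics(trials, penalty=0.0,
                                       burn_in_sessions=5)
print(f"{summaries.n_summaries} summary statistics from "
      f"{len(trials)} simulated trials")

cfg = SimConfig(n_days=40)
result = fit_agent(summaries, "multi", starts=[MANUAL_START],
                   sim_config=cfg, seed=3, maxfev=150)
est = result.params
print(f"cost {result.cost:.3f} after {result.starts[0]['nfev']} evaluations")
print(f"sigma  {est.sigma:.3f}  (truth {truth.sigma})")
print(f"lambda {est.memory_strength:.3f}  (truth {truth.memory_strength})")
print(f"T      {est.temperature:.3f}  (truth {truth.temperature})")
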