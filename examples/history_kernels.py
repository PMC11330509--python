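"""Choice-history kernels of the two POMDP agents across environments.

Simulates the best-fitting multi-trial and single-trial agents on a
60-day interleaved schedule and fits the lasso choice GLM to each
environment's choices.  The printed 1- and 2-back correct-choice weights
show the multi-trial agent's signatures: a 1- to 2-back *increase* in
the neutral environment, a negative 1-back weight (choice alternation)
in the alternating environment, and the ordering repeating > neutral >
alternating.  The single-trial agent shows a monotone decay everywhere.
"""

import numpy as np

from adaptbias import agents, glm, task
from adaptbias.fitting import environment_splits

schedule = task.generate_session_schedule(60, "interleaved_3_2", seed=11)
sessions = agents.make_sessions(schedule, 400, seed=12)

for variant in ("multi", "single"):
    params = agents.AgentParams.best_fit(variant)
    trials, _ = agents.simulate_agent(params, sessions, seed=13)
    print(f"\n{variant}-trial agent "
          f"(accuracy {100 * trials.outcome.mean():.1f} %):")
    splits = environment_splits(trials, burn_in_sessions=5)
    for env in ("repeating", "neutral", "alternating"):
        design = glm.build_design_matrix(splits[env])
        fit = glm.fit_choice_glm(design, penalty=1e-3)
        w = fit.w_correct
        print(f"  {env:12s} w+(1) = {w[0]:+.3f}, w+(2) = {w[1]:+.3f}, "
              f"w+(3..7) mean = {np.mean(w[2:]):+.3f}")
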