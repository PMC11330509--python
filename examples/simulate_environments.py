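"""Generate stimulus sequences under the three temporal regularities.

Builds a 10,000-trial sequence for each environment and measures the
realised repetition probability; sides should repeat with probability
0.8 (repeating), 0.5 (neutral) and 0.2 (alternating).
"""

from adaptbias import task

for name in ("repeating", "neutral", "alternating"):
    env = task.environment(name)
    seq = task.generate_stimulus_sequence(env, 10_000, seed=1)
    freq = task.repeat_frequency([side for side, _ in seq])
    print(f"{name:12s} p(repeat) set to {env.p_repeat:.1f}, "
          f"measured {freq:.3f}")

sched = task.generate_session_schedule(10, "interleaved_3_2", seed=2)
print("\n10-day interleaved schedule:",
      " -> ".join(env.name for env in sched))
# Three regular days then two neutral days, the behavioral experiment's
# block structure; the regular identity is re-drawn per block.
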