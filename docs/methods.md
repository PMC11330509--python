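# Methods

## Task model

The task is a two-alternative visual detection: on trial *n* a grating of
unsigned contrast c ∈ {1, 0.5, 0.25, 0.125, 0.0625, 0} appears on side
L or R; reporting the correct side yields reward r = 1, otherwise r = 0.
The side sequence is a symmetric first-order Markov chain,

P(sideₙ = sideₙ₋₁) = p_repeat,

with named presets repeating (0.8), neutral (0.5) and alternating (0.2).
The first side of a session is uniform.  Contrasts are sampled i.i.d.,
uniformly over the six levels by default (the distribution is
configurable; the empirical accuracies the acceptance script reproduces
are sensitive to this assumption).  Signed contrast is the side-signed
fraction in [−1, 1].  On 0 %-contrast trials a rewarded side is still
drawn by the transition rule, so accuracy is defined there (50 % in the
neutral environment, above 50 % for an adapted agent elsewhere).
Multi-day schedules interleave blocks of three regular days (repeating
or alternating, identity pseudo-randomised per block) with two neutral
days; a `neutral_only` pattern reproduces the recording protocol, and a
`random` pattern draws environments i.i.d.  In the 4-location variant an
independent uniform altitude (low/high) is attached to each stimulus;
the response rule ignores it.

## POMDP agents

Perception: the agent observes ŝ ~ 𝒩(s, σ²) and, with a flat prior over
signed contrast, holds the Gaussian belief 𝒩(ŝ, σ²) over s, giving
P_R = Φ(ŝ/σ) and P_L = 1 − P_R.  σ is the sensory-noise *standard
deviation* on the signed-contrast scale, bounded to [0.05, 0.5] for
fitting.  (Only this reading is consistent with the behavioral accuracy
the model reproduces: with σ ≈ 0.3 the agent's ceiling is ≈ 70 %
correct under uniform contrasts, well below the mid-to-high-70s
accuracies that both mice and the fitted model attain, whereas σ = 0.09
lands there directly.)

Memory (multi-trial variant): after a rewarded choice the next trial
carries (M_L, M_R) = (λ, 0) or (0, λ); after an error, timeout, or at a
session start the memory is (0, 0).  λ ∈ [0, 1] is the memory strength.
The extended variant instead accumulates
M = m₀ · Σᵢ exp(−(t − i − 1)/τ) over all past rewarded choices of each
side, so both activations can be nonzero; τ is measured in trials.
Memory resets overnight (session boundaries); value tables do not —
the agent learns continually across days from q ≡ 0.

Valuation and choice: Q_c = Σᵢ Pᵢ q_{c,Pᵢ} + Σⱼ Mⱼ q_{c,Mⱼ} (the memory
sum absent in the single variant); choice by softmax with temperature T
on the total Q.  Learning: δ = r − Q_C; every state entry of the chosen
row moves by α·(activation)·δ, with α⁺ for δ > 0 and α⁻ for δ < 0, the
same rate for perception and memory entries.

Default parameters are the best fits to the pooled mouse data:
multi-trial σ = 0.09, T = 0.36, α⁺ = 0.96, α⁻ = 0.97, λ = 0.07;
single-trial σ = 0.1, T = 0.4, α⁺ = 0.41, α⁻ = 1.  The single-trial
agent is exactly the multi-trial agent with λ = 0 (verified bitwise in
the tests).  Simulations expose common random numbers: with a fixed
seed the perceptual noise and choice draws are identical across
parameter settings, which makes fitted costs deterministic.

The trace records, per trial, the belief, memory, Q_L, Q_R, the
pre-choice value Q_pre = p_L·Q_L + p_R·Q_R (choice-probability
weighted), its perception and memory components separately, the chosen
value Q_C and δ.  `photometry.q_components` reweights the memory
component of Q_pre to probe expectations skewed toward memory.

## Choice-history GLM

P(R) = logistic(z) with z = Σ_c w_c I_c + Σₙ₌₁⁷ [wₙ⁺ r⁺(i−n) + wₙ⁻ r⁻(i−n)] + w₀.
Contrast indicators are one-hot over the 11 signed levels (±6 magnitudes
sharing zero), which lets the psychometric part be asymmetric.  r⁺ is
+1/−1 for a correct right/left n-back choice and 0 if that choice was
incorrect; r⁻ mirrors it for errors.  Histories never cross session
boundaries; the first 7 trials of each session and timed-out trials are
dropped (a timed-out n-back trial contributes 0 to both regressors).
Kernels stop at 7 back because the sequence autocorrelation
(2·p_repeat − 1)ⁿ is negligible beyond that lag.

The history weights carry an L1 penalty; the intercept and contrast
weights are unpenalised by default so the psychometric part stays
unbiased (a `penalize="all"` switch penalises everything except the
intercept, the glmnet convention).  The penalty is chosen from a small
grid by 10-fold cross-validated deviance, minimising deviance rather
than the 1-SE rule because unbiased kernel recovery favours minimal
shrinkage; fold assignment is deterministic given the seed.  Penalised
fits use per-coefficient-penalty L1 maximum likelihood (statsmodels);
unpenalised fits use Newton/LBFGS logistic regression (scikit-learn).
Large simulated datasets are routinely fitted with `penalty=0`: at
≳10⁴ trials the CV-selected penalty is near zero and the unpenalised
fit is an order of magnitude faster.

`simulate_from_kernels` is the recovery forward model: choices are
sampled trial by trial from postulated weights so the history regressors
reflect the simulated, not the template, choices.  Recovery of planted
kernels achieves r ≥ 0.9 regardless of which environment's stimulus
statistics drive the simulation.

## Psychometric curve and exclusion

P(R) = γ + (1 − γ − λ)·F(c; α, β) with
F = 1/(1 + exp(−(c − α)/β)): γ and λ are the right and left lapse
rates (bounded [0, 0.5]), α the bias in contrast-fraction units
(matching the 0.16 exclusion threshold) and β the threshold/scale.
Maximum likelihood by bounded L-BFGS-B from a small grid of starts.
Sessions are excluded when |α| > 0.16, max(γ, λ) > 0.2 or 100 %-contrast
accuracy < 0.8; trials with response time > 12 s are dropped.  Exclusion
is idempotent and reports per-session flags and counts.

## Agent fitting and model comparison

The cost is the summed squared difference between empirical and model
summary statistics: per-environment contrast weights (3 × 11), the
1–7-back correct-choice kernels of the three environments, and the
kernels of neutral sessions split by the preceding day's regularity
(5 × 7), 68 entries in total.  The exact summary composition is
configurable; `n_summaries` flows into the F-test/BIC rather than being
hard-coded.  Model summaries come from simulating the candidate on a
*deterministic balanced* interleaved schedule (cycling 3 repeating /
2 neutral / 3 alternating / 2 neutral days) so that every split exists
at any day count; with a fixed simulation seed the cost is deterministic
in the parameters.  Inner GLM fits are unpenalised for speed.

Optimisation is bound-constrained Powell search (any derivative-free
optimiser serves; the published result is a cost minimum, not an
optimiser identity), repeated from a start grid of low/high learning
rates × weak/strong memory (σ = 0.1, T = 0.3) plus one manually-tuned
start (0.14, 0.34, 0.95, 0.95, 0.05).  Parameter bounds:
σ ∈ [0.05, 0.5], T ∈ [0.01, 1], α± ∈ [0.01, 1], λ ∈ [0, 1].  On
synthetic data with ≥ 4×10⁴ trials per environment a single polished
start recovers λ within ±0.03 and σ within ±0.02; the learning rates
are only weakly constrained by these summaries (a flat cost direction,
also visible in repeated fits).

Nested models are compared with
F = ((RSS_r − RSS_f)/(k_f − k_r)) / (RSS_f/(n − k_f)) and
BIC = n·ln(RSS/n) + k·ln n on the summary residuals, ΔBIC =
BIC_reduced − BIC_full (positive favours the full model).

## Engagement GLM-HMM

Two hidden states, each emitting choices from a Bernoulli GLM on
[signed contrast, 1].  Fitting is EM: scaled forward–backward per
session in the E-step; maximum-likelihood transition and initial-state
estimates plus posterior-weighted logistic regressions in the M-step.
No priors on transitions.  Best of `n_init` random initialisations
(sticky transition seeds, random slopes); states are canonically
ordered by stimulus slope, so state 0 is the engaged state.  The
per-iteration log-likelihood is recorded and checked monotone; the
forward likelihood is verified against brute-force path enumeration for
short sequences.  Hard labels use the maximum smoothed posterior;
Viterbi decoding is available as an option (the two agree on sticky
data).

## Photometry

Channels are acquired by alternating 470/415 nm excitation at 40 Hz
(20 Hz per channel, half-frame offset) and brought onto the 470 time
base by linear interpolation.  Preprocessing per session: least-squares
affine fit of control to signal (an intercept is included; a pure
"linear fit" is recovered when the data demand it),
ΔF/F = (signal − fitted)/fitted, high-pass by subtracting a centred
25 s moving average (window shrinks at the edges), z-score.  ΔF/F is
invariant to a common gain on both channels, and identically zero when
the signal is an affine function of the control.

Event alignment baselines each trial to its −0.5–0 s pre-stimulus mean;
a `previous` mode baselines to the preceding trial's pre-stimulus
window instead (carryover control: it leaves the current pre-stimulus
samples free).  The per-trial dopamine scalar is the mean over
0–0.6 s post-stimulus, truncated at each trial's outcome time so reward
responses never leak in; the window extent is configurable because it
is known only graphically.

ΔQ/ΔDA: for each lag n, mean(value | current side = n-back side) −
mean(value | different), restricted to pairs where both trials were
rewarded and lie in the same session exactly n trials apart.  Applied
to Q_pre or Q_C this gives the model curve (the 1- vs 2-back ordering
is stable across the pre/post-choice choice); applied to measured
scalars, the dopamine curve.

## Synthetic data generator

The generator composes schedule → sequences → agent and renders the
latents into photometry.  What it emulates: session structure and
transition statistics; response times (lognormal, median 0.5 s,
σ_log = 0.7, truncated at 12 s); inter-trial intervals uniform 1–3 s; a
0.7–0.8 s pre-stimulus hold; and a lognormal wheel-quiescence re-arm
delay (median 2.1 s) between ITI and hold — with these defaults the
median inter-stimulus interval is ≈ 5.55 s, matching the recording
sessions.  The hold+RT+ITI components alone cannot reach that spacing;
the re-arm term models the wait for the animal to still the wheel and
is the package's own timing choice.

Photometry: 470 = bleach + shared artifact + transients + white noise;
415 = bleach + shared artifact + noise.  Bleaching is exponential
(τ = 1200 s) onto a 60 % floor; the artifact is smoothed Gaussian noise
added to both channels in proportion to channel brightness (so the
isosbestic regression can remove it); transients convolve per-event
impulses — stimulus amplitude ∝ Q_pre, outcome amplitude ∝ δ — with a
double-exponential kernel (50 ms rise, 1 s decay, ultra-fast-sensor
scale), scaled by the surviving fluorophore pool so ΔF/F gain is stable
under bleaching.  What it does **not** emulate: hemodynamic or fiber
optics, wheel kinematics, licking artifacts, hemisphere/laterality
structure, non-exponential bleaching, or reward-epoch sensor
saturation.  Passing tests therefore certify the analysis chain and the
model's internal consistency, not robustness to every artifact of real
recordings.

## Problem sizes and numerical choices

Simulated datasets use ~400 trials/session (the empirical scale).
Signature checks that hinge on the multi-trial agent's large effects
(1-to-2-back increase ≈ −0.15 in kernel units, ΔQ(2) − ΔQ(1) ≈ 0.08)
use 100–150 sessions; the single-trial agent's corresponding effects
are an order of magnitude smaller (+0.025 and +0.011, with
between-dataset SD ≈ 0.02 at 100 sessions from slow value wander), so
its checks use 400-session datasets.  Agent-fitting checks use
≥ 4×10⁴ trials per environment for the reference data and an 80-day
balanced schedule per cost evaluation, 250–400 evaluations per start.
Softmax logits and logistic arguments are clipped at ±700 before
exponentiation; lapse/EM probabilities are clipped away from 0/1 by
1e-12; EM returns its best iterate with a warning when the tolerance is
not met within the iteration cap.  Ties in δ (δ = 0) produce no update,
so the α⁺/α⁻ branch is immaterial there.

## Known limitations

- Fitting targets pooled summary statistics; per-subject hierarchical
  fits are out of scope.
- The learning rates α⁺/α⁻ are weakly identified from kernel summaries
  alone; recovered values can sit far from the generating ones without
  affecting the kernels (the cost landscape is flat along that
  direction).
- The error-choice (w⁻) kernels of real mice reflect disengagement
  episodes that the agents do not produce; the generator plants
  engagement structure only through the agents' softmax noise, so
  engaged/disengaged splits on generated data are near-degenerate
  unless disengagement is planted explicitly (as the HMM examples do).
- The exact stimulus-response window and the summary composition behind
  the published degrees of freedom are only partially specified; both
  are exposed as configuration rather than fixed.
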