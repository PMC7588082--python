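# Methods

## The task and its synthetic generator

The modelled task is a 120-trial probabilistic reward learning game. On each
trial the subject chooses between a blue and a green card; one card wins and
pays the reward value (an integer 1–9) printed on it. Between the cards an
animated face gazes at one of them. Two independent binary probability
schedules drive the trial outcomes:

* **card stream** — P(blue wins): 0.73 on trials 1–60 (stable phase), then
  0.27 / 0.73 / 0.27 in blocks of 20 (volatile phase, 3 reversals);
* **gaze stream** — P(gaze points at the winning card): 0.73 on trials 1–30
  (stable), 0.27/0.73/0.27/0.73 in blocks of 10 over trials 31–70 (volatile,
  5 reversals), then 0.27 on trials 71–120 (stable). The *incongruent-first*
  counterbalancing flips the gaze schedule pointwise (1 − p).

The task design fixes the phase windows, the 0.73/0.27 stable levels and
the 5-versus-3 reversal counts; the interior reversal trial indices of the
volatile phases are not pinned down by the design constants, so the block
boundaries above are declared approximations chosen to satisfy the printed
phase windows and reversal counts. All levels and boundaries are configurable
(`ScheduleConfig`).

Rewards are independent uniform integers 1–9 per card per trial (only the
range is specified by the design). Responses are coded in the *gaze frame*:
y = 1 means the advice was followed. Synthetic cohorts contain no missed
trials; the trial-table reader tolerates and flags missing rows.

Reversal counting requires a predecessor, so trial 1 never counts as a
change. Trial indices are 1-based in files and documentation, 0-based in
arrays.

## Perceptual models

Both streams are filtered independently; choices never feed back into the
filters, because each trial's outcome reveals both the winning card and
(hence) whether the gaze was correct — full-information inputs.

**Three-level binary HGF.** Level 1 is the binary outcome; level 2 its
tendency in logit space; level 3 the log-volatility of that tendency. Per
trial, a prediction step propagates the previous posteriors
(μ̂₂ = μ₂, μ̂₁ = s(μ̂₂), π̂₂ = 1/(σ₂ + e^{κμ₃+ω₂}), π̂₃ = 1/(σ₃ + e^{ω₃})),
and an update step applies precision-weighted prediction errors
(π₂ = π̂₂ + μ̂₁(1−μ̂₁), μ₂ = μ̂₂ + δ₁/π₂, and the standard level-3 update with
weighting factor w₂ = e^{κμ₃+ω₂}·π̂₂ and volatility prediction error δ₂).
The derived learning-rate series are ψ₂ = 1/π₂, q(ψ₂) = ψ₂·s(μ₂)(1−s(μ₂))
(an uncertainty measure for first-level beliefs that corrects for the sigmoid
link), and ψ₃ = π̂₂/π₃.

Free parameters per stream: ω₂ (tendency evolution rate) and ω₃ (volatility
evolution rate). κ is fixed to 1 and not estimated. Levels 2–3 support an
AR(1) drift toward an attractor, with the coefficients fixed to zero (pure
Gaussian random walk) by default — the conventional configuration; no prior
information exists for the AR coefficients.

*Initial states.* μ₂(0) = 0, σ₂(0) = 1, μ₃(0) = 1 — fixed, not estimated.
σ₃(0) defaults to **0.5**, i.e. level 3 starts near its stationary posterior
variance under the default evolution rates (long-run π₃ ≈ 2.15 at ω₂ = −3,
ω₃ = −6). Starting it at 1 puts a session-long upward transient into π₃,
which tilts ψ₃ downward through the session and confounds stable-versus-
volatile phase contrasts (the card stream's stable phase is exactly the first
half of the session). This is the steady-state initialization familiar from
Kalman filtering; it is configurable like every other initial state.

*Numerical guards.* μ̂₁ is clipped to [1e−8, 1−1e−8] before the Bernoulli
precision 1/(μ̂₁(1−μ̂₁)) is formed; a non-positive or non-finite level-3
posterior precision raises a rejection error carrying the trial index, which
the fitter converts into a large penalty (−1e10) so that line searches remain
finite.

**Rescorla–Wagner.** v(k) = v(k−1) + α(u(k) − v(k−1)) per stream, v(0) = 0.5,
α ∈ [0,1] estimated in logit space.

**Sutton K1.** A delta rule whose gain adapts multiplicatively: the log-gain
moves by μ·δ(k)·h(k−1), where h is a decaying trace of recent weighted
prediction errors, so the gain rises when current and recent errors agree in
sign; the gain is bounded to (0, 1]. Initial gain fixed at 0.1; the
meta-learning rate μ is estimated in log space (the standard K1
parameterization used in hierarchical-filtering toolboxes).

## Response models

The trial-t social prediction μ̂₁,gaze (gaze correct) and the gaze-frame
non-social prediction μ̂₁,card (the gazed-at card's color wins) are combined
with weights derived from their Bernoulli precisions π̂ = 1/(μ̂(1−μ̂)), the
social one scaled by the social weighting factor ζ > 0:

  w_gaze = ζπ̂_gaze / (ζπ̂_gaze + π̂_card),  b = w_gaze μ̂₁,gaze + w_card μ̂₁,card.

The follow probability is a reward-weighted softmax mixing linear and
logarithmic reward weighting with weight η ∈ [0,1]:

  P(y=1) = η σ(γ(r_g b − r_n(1−b))) + (1−η) σ(γ(ln r_g · b − ln r_n (1−b))),

where r_g/r_n are the rewards on the gazed-at/other card. The inverse
temperature γ(t) defines four variants: (1) β e^{−μ̂₃,card−μ̂₃,gaze},
(2) β e^{−μ̂₃,gaze}, (3) β e^{−μ̂₃,card}, (4) β. Variants 1–3 require the HGF;
the non-hierarchical learners pair with variant 4 only. The γ exponent is
saturated at ±600 — beyond that the softmax is already deterministic and
unguarded exponentials would overflow.

Two non-learning baselines close the model space of eight: **win-stay-
lose-shift** (stay with the previously chosen card after a win, switch after
a loss, executed with error probability ε, mapped into the gaze frame; trial
1 and trials after a missed trial get probability 0.5) and **random
responding** (a constant follow bias, estimated in logit space rather than
fixed at 0.5 so the model has a fitted evidence). Both are the minimal
ε/bias-noisy stochastic versions of these classic strategies that admit a
likelihood.

## Inversion

MAP estimation under independent Gaussian priors in transformed spaces
(native for ω's, log for ζ, β and the K1 meta-rate, logit for η, α, ε and
the follow bias). Defaults:

| parameter | space | prior |
|---|---|---|
| ω₂ (both streams) | native | N(−3, 16) |
| ω₃ (both streams) | native | N(−6, 16) |
| log ζ | log | N(0, 4) |
| log β | log | N(log 48, 1) |
| logit η | logit | N(0, 4) |
| logit α, logit ε, logit bias | logit | N(0, 1) |
| log μ (K1) | log | N(0, 4) |

The decision-noise prior follows the customary softmax configuration centred
at β = 48: with the volatility attenuation e^{−μ̂₃,card−μ̂₃,gaze} ≈ e^{−2} this
gives moderate effective temperatures; centring log β at 0 instead makes half
of a priors-dispersion cohort behaviorally random and destroys the
identifiability of every other parameter.

The optimizer is L-BFGS-B with numerical gradients, started at the prior mean
plus seeded Gaussian perturbations (SD = prior SD/4; 4 restarts by default, 2
in the routine-scale studies), objective tolerance 1e−6 (absolute; the
relative ftol is divided by a typical objective scale of 100). The log model
evidence is the Laplace approximation LME = log p(y,θ*) + (d/2)ln 2π −
½ ln det(−H), with H the central-finite-difference Hessian (step 1e−4 per
dimension); a non-positive-definite −H is diagonally regularized and flagged.
Fits are bit-reproducible given data, config and seed.

## Group-level model selection

Random-effects BMS: a Dirichlet(α₀=1) prior over population model
frequencies, variational updates alternating subject-level assignment
responsibilities u_nk ∝ exp(LME_nk + ψ(α_k) − ψ(Σα)) with α = α₀ + Σ_n u_n,
iterated to max|Δα| < 1e−6. Reported: expected posterior probabilities
EXP_R = α/Σα; exceedance probabilities XP by Monte-Carlo argmax frequency
over Dirichlet(α) draws (10⁶ by default, seeded, with the MC standard error);
the Bayes omnibus risk BOR = 1/(1+e^{F₁−F₀}) comparing the RFX free energy F₁
against the null of equal frequencies F₀ = Σ_n(logsumexp_k LME_nk − ln K);
and the protected exceedance probabilities PXP = (1−BOR)·XP + BOR/K. All
outputs are invariant to per-subject LME shifts.

## Validation analyses and their cohorts

**Behavioral summaries.** High-probability choice: the chosen card's
ground-truth winning probability ≥ 0.5 (card cue), or following exactly when
gaze accuracy ≥ 0.5 (gaze cue); ties at 0.5 count as high (inert on the
canonical schedules, which never hit 0.5). Advice taking = follow rate split
by social accuracy (high/low) × gaze-stream stability. Cells with no observed
trials are reported absent (NaN), never zero. Group-level inferential tests
(mixed ANOVAs) are delegated to standard statistical software via the
exported tidy tables; their internals are not re-implemented.

**Parameter recovery** follows the estimate-centred protocol: a cohort is
drawn from the *default priors* themselves, fitted once, and each subject is
then re-simulated from the fitted estimates and refitted (replicate-mean
recovered value vs. first-pass estimate, Pearson r). Conditioning on
estimates matters: raw prior draws of the barely identifiable ω₃'s (SD 4)
shift the μ̂₃ trajectories and hence the effective temperature, a confound
that caps r(log β) near 0.55; the estimates live in the identifiable manifold
and recovery around them reaches r ≥ 0.9 for log ζ, log β and both ω₂'s,
while the ω₃'s recover poorly — as expected. Subjects whose prior draw
produces an invalid belief trajectory are redrawn (the generating
distribution is truncated to the filter's domain).

**Model recovery** cohorts (n = 30 per generating model) use estimation-space
SD 0.5 around ω₂ = −3, ω₃ = −6, log ζ = 0, logit η = 0 and log β = 2 — an
engaged-agent decision-noise magnitude (the representative single-subject
posterior has log β = 2.21). All eight models are fitted to every subject and
the LME matrix passed to RFX-BMS; the generating model should take XP > 0.9.

**Precision-weight phase effect.** Fifty default-parameter agents on
canonical schedules; cohort-mean q(ψ₂) and ψ₃ are compared between each
stream's own stable and volatile windows. Both rise under volatility for both
streams (direction only).

**ζ-alignment.** Agents share perceptual parameters and differ only in
log ζ ∈ {−5..5}. Alignment with each input structure is the *partial*
regression coefficient of the combined belief b(t) on the two ground-truth
schedules jointly (gaze accuracy; gaze-frame card schedule). Marginal
agreement measures (correlation or MSE against either the binary inputs or
the schedules) peak at an interior ζ because the two streams' predictions are
mutually informative — a card-informed belief genuinely helps predict gaze
correctness — so only the partial coefficients answer "which structure does
the belief follow". They are monotone across the grid (gaze non-decreasing,
card non-increasing); raw correlations are reported alongside.

**Lagged-regression choice analysis.** Per subject, frame (card/gaze) and
phase, a binomial-family GLM of the choice on the outcomes at lags 1–5 plus
the two displayed-reward predictors; trials whose lag window crosses a phase
boundary are excluded. The logistic link is the default (the outcome is
binary); a linear-probability fit is available behind ``family="linear"``.
Perfect or quasi-separation (detected via the fitting warning or exploding
coefficients) falls back to a small ridge penalty (1e−4), flagged in the
result. The "lag slope" is the least-squares slope of coefficient against lag
index 1..5; more negative = stronger recency weighting. The phase contrast is
a paired t test on per-subject slopes.

*Known negative result.* For simulated HGF agents the volatile-steeper-slope
direction does **not** emerge: at n = 300 agents (default parameters or the
reference posterior; either link) the mean volatile-minus-stable slope
difference is statistically zero. The model's within-session learning-rate
modulation (a few percent in q(ψ₂)) is swamped by the block autocorrelation
of volatile-phase outcomes, which spreads apparent weight across all lags and
flattens the fitted profile. Human cohorts evidently adapt more strongly than
these agents; the corresponding acceptance check is expected to fail and is
kept honest rather than tuned.

**Posterior predictive checks** re-simulate each subject n_rep times from
their fitted parameters on their own experiment and recompute the behavioral
summaries (n_subjects × n_rep simulated datasets before per-subject
averaging). The two-group pipeline test (high-ζ vs low-ζ cohorts) verifies
that the group-by-cue accuracy pattern present in directly simulated behavior
survives fit-and-resimulate.

## What the synthetic cohorts do and do not show

The generator reproduces the task's design constants exactly and produces
agents whose behavior carries the modelled structure. It does not emulate
real participants' attention lapses, missed trials (cohorts are complete by
construction), session-order effects, or the heavier between-subject
heterogeneity of clinical groups. Passing tests therefore demonstrate the
internal consistency and statistical validity of the pipeline — recovery,
selection, phase sensitivity — not that any specific clinical effect size
would replicate.

## Problem sizes used in the standing checks

Routine runs use reduced sizes chosen as the package's own defaults: recovery
20 subjects × 2 replicates (tests) or 50 × 3 (reproduction script), model
recovery 30 subjects per cohort with 2 optimizer restarts, phase and GLM
cohorts of 50, alignment curves averaged over 10 experiments. The
posterior-predictive bookkeeping check runs the full 116 × 10 = 1160
simulations with simulated subjects standing in for fitted ones, since the
count does not depend on fit quality.
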