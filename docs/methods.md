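# Methods

## The model

Training-phase choice mixes two learners that both map stimulus–action values
to probabilities through a softmax with a fixed, high inverse temperature
β = 50 (fixed because a free temperature trades off against the learning rate
and WM reliance; choice stochasticity is carried by the mixture weights
instead).

**RL actor.** `Q(s,a)` starts at `1/n_a` (all actions equally likely,
`n_a = 3`) and follows a Rescorla–Wagner delta rule with learning rate
`α_RL` on correct trials (reward coded 1) and `α_RL·γ` on incorrect trials
(reward 0). `γ ∈ [0,1]` is punishment neglect: `γ = 0` ignores errors
entirely.

**WM store.** `WM(s,a)` also starts at `1/n_a`. A correct outcome sets the
observed entry to exactly 1 (one-shot encoding); an error moves it toward 0
with rate `γ` (the same neglect factor, applied with an instantaneous
learning rate). After every trial, all entries except the observed
(stimulus, action) pair relax toward the `1/n_a` prior with decay rate `φ`.
The exemption scope is switchable (`ModelOptions.pair_level_decay`): the
default exempts only the observed pair (the literal reading of
"not observed"); the alternative exempts all actions of the current stimulus.

**Mixture.** `p = (1−ω)·p_RL + ω·p_WM` with `ω = ρ·min(1, WM_cap/n_delay)`.
`ρ ∈ [0,1]` is the baseline propensity to rely on WM; `WM_cap ∈ {2..5}` is an
integer capacity; `n_delay` counts the *unique other stimuli* presented since
the stimulus's last correct response. Counters start at 0 per block (the min
term is defined as 1 when `n_delay = 0`) and reset on each correct response.
Note this is a stimulus-identity count, not a trial count — the regression
variable "delay" in the behavioral analyses *is* a trial count; the two are
deliberately different quantities.

**Test phase.** A critic `V(s)`, initialized at `1/n_a` and updated at the
actor's rate (same `α_RL`, same `γ` discount on errors), feeds a two-option
softmax (same β) mixed with uniform guessing:
`p(choose a) = ν/2 + (1−ν)·σ(β·(V_a − V_b))`. By default the critic learns
from the binary correct/incorrect code; a point-coded mode (0/1/2 points,
`ModelOptions.point_critic`) is available because the task's test instruction
is about points. Model fits are insensitive to this distinction here, as the
points are performance-independent given correctness.

**Within-trial order** (identical in simulation and likelihood, which is what
matters for fitting consistency): compute choice probability → update delay
counters (presenting `s` marks it as intervening for every other stimulus;
a correct response resets `s`'s counter) → RL/WM/critic updates for the
observed pair → WM decay. State resets at each block start; stimuli are
unique across blocks, so the critic table is effectively per-block too.

Free parameters and bounds: `α_RL, γ, φ, ρ, ν ∈ [0,1]`, `WM_cap ∈ {2..5}`;
β is a constant, overridable only through `ModelParams.beta` for sensitivity
analyses.

## Estimation

Per subject-session MAP: for each `WM_cap` in 2..5, maximize
log-likelihood + log-prior over the five continuous parameters with
multi-start bounded L-BFGS-B (default 20 restarts; the first start sits at
the center of the empirically plausible region, the rest are uniform draws);
the capacity with the best optimum wins, smallest capacity on exact ties.
Priors: uniform on `α_RL`, `ρ`, `WM_cap`; Beta(1.05, 1.05) on `φ`, `γ`, `ν`
— just enough density curvature to keep those parameters off the bounds. The
training and test phases enter the likelihood jointly by default
(`FitConfig.include_test_phase=False` gives the training-only ablation).
Likelihood evaluation is a numba-compiled kernel (≈40 µs per session);
sessions are packed into flat arrays once per fit.

Two estimator details deserve emphasis:

1. **Log-scale search for `α_RL`.** The scientifically meaningful regime
   (α below ~0.05; fitted values in this paradigm are ~0.00–0.04) occupies a
   sliver of the linear [0,1] axis. The optimizer searches `log10 α` over
   [−5, 0] with restarts uniform on that scale. The objective is unchanged;
   only the search geometry is. Linear search remains available
   (`FitConfig.alpha_log_search=False`).

2. **Label-switching resolution.** The model has a mirror solution in which
   the roles swap: the RL actor does the one-shot learning (large `α_RL`)
   while the WM store, decaying within a trial (`φ → 1`, small `ρ`), acts as
   a constant lapse process. The two labelings make nearly identical
   trial-level predictions, so their log-posterior difference at session
   scale (~360 trials) is dominated by sampling noise (sd of a few nats);
   the unconstrained global optimum lands in the mirror mode for roughly one
   session in ten, with "wins" of 1–5 nats that carry no evidential weight.
   Because the model is only interpretable — and parameters only comparable
   across subjects — under the slow-RL/fast-WM labeling, the estimator by
   default returns the best optimum with `α_RL ≤ 0.1` and reports any
   unconstrained advantage in `FitResult.fast_mode_advantage`.
   `FitConfig.resolve_role_degeneracy=False` gives the unconstrained MAP.

Outlier screening for group-level analyses: within each session group,
remove a subject when any screened parameter deviates from the group mean by
more than 2 sample standard deviations (single pass; zero-variance parameters
exclude nobody; groups under 3 pass through flagged).

## Task generator

Defaults: set sizes (2,3,4,5) with (3,3,2,2) blocks respectively → 10 blocks,
297 training trials; nine iterations per stimulus; three actions assigned
uniformly at random (several stimuli may share a button); +2 points with
probability 0.8 and +1 with 0.2 on correct trials, 0 on errors. Sequences
shuffle each iteration sweep and forbid immediate repeats, so every stimulus
appears exactly once per sweep. The block split is a package choice within
the stated "2–3 blocks per set size" envelope (more blocks for smaller sets
keeps the session length moderate) and is fully configurable. Test pairs are
built in shuffled round-robin rounds — default 4 per stimulus (~66 pairs),
never pairing a stimulus with itself, presentation side randomized.

## Synthetic cohorts

`PopulationSpec` embeds simulated agents in the study's covariate structure:
a standardized dopamine-synthesis proxy per subject (standard normal), three
drug sessions (PBO/MPH/SUL) in rotated (counterbalanced) order, and a
covariate→parameter effect map. Link functions are conveniences of this
package, not part of the cognitive model: unit-interval parameters shift on
the logit scale; capacity shifts additively, then rounds and clips into
{2..5}. Default effects (logit-scale): +0.3 dopamine-proxy on ρ, −0.4
sulpiride on ρ, +0.3 methylphenidate×proxy on α_RL, +0.3 sulpiride on φ —
directions follow the group-level findings this paradigm is known for;
magnitudes are loosely scaled placeholders for recovery exercises, not
estimates. Base parameters at covariate zero: α_RL 0.02, γ 0.44, φ 0.15,
ρ 0.85, cap 3, ν 0.08 (centers of the plausible fitted ranges).

`kappa_effort ≥ 0` (default 0) devalues test-phase stimulus values by
`kappa · set_size` at choice generation only — the minimal mechanism for an
implicit effort cost; training behavior is untouched. Response times are
lognormal (median 1.07 s, σ = 0.4) purely so the 250 ms filter is
exercisable; they model nothing cognitive. The generator does not emulate
real-data features beyond this: no within-session drift, no attention
lapses correlated across trials, no RT–accuracy coupling, no dropout beyond
missing-session handling — so passing self-consistency checks demonstrates
internal correctness of the pipeline, not fidelity of the model to human
data.

## Validation harnesses and what they show

**Recovery** (`run_recovery`): truths uniform over the plausible fitted
ranges (α_RL [0, .04], γ [.039, .84], φ [0, .30], ρ [.62, 1.0], cap {2..5},
ν [.026, .14]), one session per subject on a fresh default design,
MAP refit, Pearson r per parameter plus a capacity confusion matrix.
Measured at 90 subjects (seed-to-seed variation ±0.1): r ≈ 0.55–0.67 for
α_RL, ≈ 0.46–0.61 for γ, ≈ 0.40–0.48 for φ, ≈ 0.44–0.59 for ρ; capacity
exact-match ≈ 0.48–0.58. The φ/ρ ceiling is informational, not an optimizer
defect: truth-started local optimization does not beat the returned optima,
and even one-dimensional maximum likelihood with all other parameters held
at truth yields r(φ) ≈ 0.4 — "WM decaying quickly + relied on less" and
"WM intact + relied on more" differ only through delay-conditional error
structure, which at β = 50 and ~360 trials per session carries a nat or two
of likelihood against several nats of noise.

**Posterior predictive checks** (`run_ppc`): each subject re-simulated at
its MAP estimates on its own realized stimulus sequences (conditioning on
the design isolates model misfit from design variance), accuracy curves by
set size × iteration compared cell-wise. On a 200-subject self-consistent
cohort the maximum cell discrepancy is ≈ 0.03–0.05 with a mean signed
difference ≈ 0.

**Set-size ordering.** A structural note: with `WM_cap = 3`, `n_delay`
(unique intervening stimuli) is bounded by set_size − 1, so the capacity
ratio saturates for set sizes 2–4 and the model produces *no* capacity-driven
accuracy ordering among them — only the φ-decay gradient (~0.003 at
φ = 0.05) separates them, far under sampling noise at a 200-agent cohort.
Only set size 5 separates cleanly. Graded orderings like the empirical ones
arise from populations with mixed capacities and larger decay, not from a
single cap-3 agent.

## Numerical choices

- Softmax in log-space with max-subtraction; finite for β = 50 by
  construction. Test-phase probabilities floored at 1e-300 before `log`.
- Beta-prior parameters are kept strictly inside (0, 1) (bounds at 1e-6)
  since the Beta(1.05, 1.05) density vanishes at the endpoints; the prior
  itself is a hand-coded log-density (two logs and a constant) for per-eval
  speed, verified against `scipy.stats.beta` in the tests.
- Capacity ties break toward the smaller capacity (parsimony); the
  `rho = 0` reduction makes all capacities exactly equivalent and the
  tie-break then selects 2.
- Outlier screening uses the sample SD (ddof = 1), single pass.
- Optimizer: L-BFGS-B, ftol 1e-9, maxiter 1000; identical restart points
  are shared across the capacity grid so capacities are compared fairly.
- Degenerate inputs: zero-variance recovery samplers yield NaN correlations
  with a flag rather than an error; empty sessions are flagged and excluded
  session-wise; groups too small for the ±2 SD screen pass through flagged.

## Problem sizes used by the test suite and acceptance script

Cohort-scale checks run at 90 subjects (recovery), 200 subjects × 20 draws
(posterior predictive self-consistency in the tests; 120 × 10 in the
acceptance script), 200 agents (ordering), and 100 seeded cohorts of 30
subjects (effort-discounting sign rate; generator at `kappa_effort = 0.03`,
cohort γ = 0.5, ν = 0.05). These sizes give stable statistics on one CPU in
minutes.

## Known limitations

- φ and ρ are weakly identified from single sessions (see Recovery above);
  cohort-level contrasts remain meaningful, per-subject point estimates of φ
  should be treated with caution.
- ν is poorly constrained by ~66 test pairs and shows a positive bias at
  single-session scale.
- The label-switching resolution is a hard classification at `α_RL = 0.1`;
  sessions genuinely governed by fast RL (none expected in this paradigm)
  would be mislabeled — inspect `fast_mode_advantage` when in doubt.
- The fixed-effects logistic regression is a stand-in for hierarchical
  trial-level models: use it for signs and qualitative structure, not for
  population-level inference.
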