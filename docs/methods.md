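# Methods

This note documents the models, the task environment the synthetic-data
generator emulates, the estimation procedures, and the numerical and design
choices behind them.

## Task environment

The environment is a center-out reaching task with an angular visuomotor
perturbation p_t = α + ε_t between hand and cursor. α is a constant bias
(0°–40° across groups in the emulated study designs). ε_t is zero-mean
uniform noise whose half-width grows linearly with the absolute angular
distance δ_t between the *selected target* and a fixed per-participant
least-noisy direction φ, at 1/6 degree of half-width per degree of distance
(maximum 30° at δ = 180°). Tying the noise to the target rather than the
reach direction is what makes target selection the instrument for noise
reduction.

Two protocols are generated:

* **Protocol 1**: 400 choice trials (three targets spaced 120° at a
  uniformly random orientation per trial) followed by 24 no-feedback probe
  trials (8 equally spaced directions × 3 repetitions, shuffled).
* **Protocol 2**: 200 single-target training trials (uniformly random
  direction, bias only, no noise), then 200 choice trials with bias + noise,
  then 24 probes.

φ is drawn uniformly per simulated session unless pinned in the
configuration. Probe trials provide no feedback: the adaptation state decays
but is not error-updated, and no perturbation is stored for them. Screen
geometry, cursor kinematics, hold periods and reward accounting of the
online task are not simulated; the agent's sampled choice is taken as the
chosen target directly, since both learners operate only on the chosen
direction and the feedback error.

## Reach-adaptation model

A single-rate state-space learner over a circular state p̂(θ):

* planning: y_t = −p̂_t(θ_t);
* prediction error from feedback: d_t = p_t − p̂_t(θ_t);
* update: p̂_{t+1}(θ) = a·p̂_t(θ) + b·G(θ, θ_t)·d_t, with the periodic
  kernel G(θ,θ′) = exp(−2 sin²((θ−θ′)/2)/l²).

Parameters: retention a ∈ [0,1] (applied globally every trial, including
unvisited directions and probe trials), learning rate b ∈ [0,1], and
dimensionless kernel length-scale l > 0 acting on radian arguments (the
pooled estimate l = 0.46 confines generalization to a few tens of degrees).
The generative model contains no motor noise: the only stochasticity in a
simulated session is the perturbation draw and the categorical choice.
Useful closed form (used as a test oracle): under a constant perturbation α
at one practiced direction, the residual error converges to
α(1−a)/(1−a+b) — at the pooled parameters and α = 40° this is 9.03°, i.e.
adaptation is persistently incomplete.

## Target-selection models

All variants choose among the three offered targets by a softmax over a
learned per-direction value, P(i) ∝ exp(−β v(θ_i)), with decision-noise
parameter β in units of 1/degree (value functions are in degrees; β = 0 is
chance, larger β concentrates choice on the smallest value).

* **Expected loss** (`loss`): v = L̂. Delta rule
  L̂(θ) ← L̂(θ) + η K(θ,θ_t)(L_t − L̂(θ_t)) with observed loss
  L_t = |feedback error| and periodic kernel K of length-scale λ. L̂ is
  initialized to the first observed loss, equally for all directions; the
  first choice trial is therefore scored with uniform probabilities.
* **Expected signed error** (`bias`): the same delta rule on the signed
  feedback error R_t, with v = |R̂|. The initialization mirrors the loss
  variant (first observed signed error); a zero-initialization switch is
  exposed because the deferred rule is a modeling choice, not forced by the
  update equations.
* **Perturbation SD** (`noise`): a one-pass, kernel-weighted running
  standard deviation of the perturbation per direction, tracking fractional
  sample counts N, running means M, and SDs S:

      N⁺(θ) = N(θ) + K(θ,θ_t)
      M⁺(θ) = (N M + K p_t) / N⁺
      S⁺²(θ) = (N S² + K (p_t − M⁺(θ_t))(p_t − M(θ_t))) / N⁺

  The third line updates S²; the cross product is evaluated at the chosen
  direction and is non-negative because M⁺(θ_t) lies between M(θ_t) and
  p_t, so S² never goes negative. With every trial at one direction
  (K = 1 there) the recursion is exactly Welford's algorithm and S equals
  the population SD (denominator n) of the observed perturbations — this
  equivalence is asserted to 1e-9 in the tests. N is floored at 1e-12 in
  divisions purely as an underflow guard; analytically K > 0 everywhere.

## State representation

Per-direction functions are stored on a uniform circular grid (default 1°,
360 nodes; any resolution dividing 360 is accepted). Learning updates are
applied exactly at the nodes using the kernel evaluated at the true
(continuous) trial direction. Evaluation at arbitrary directions uses
periodic **linear interpolation** between the bracketing nodes rather than
nearest-node lookup: with interpolation the discretization error is bounded
by curvature·h²/8 (≈ 0.01° for the estimates arising at behavioral
parameters on a 1° grid), and replaying a full session at 1° vs 0.25° grids
changes predicted reach angles by less than 0.1° everywhere, which
nearest-node lookup cannot guarantee on the steep kernel flanks.

## Closed-loop simulation

`run_session` couples the two learners in the environment: per choice trial
it samples the option triplet, computes softmax probabilities from the
selection state, samples the choice, plans the reach, draws the
perturbation, computes the signed error and loss, and updates both
learners. Training trials engage only the reach learner (noise-free bias);
probes record the planned reach and decay the adaptation state. Sessions
carry their ground-truth parameters and seed. Cohorts derive independent
per-run seeds from a master seed via `numpy.random.SeedSequence`
(`generate_state`, masked below 2³¹), and redraw φ per run unless pinned.

The generator's defaults are the emulated study conditions: pooled
parameters a = 0.986, b = 0.048, l = 0.46, η = 0.039, λ = 0.80, β = 0.15;
protocol counts 400/24 and 200/200/24; noise slope 1/6; bias angles set per
cohort group. What the generator does **not** emulate — motor execution
noise, device anisotropy, attention lapses, trial exclusions arising from
mid-movement changes of mind — means that passing recovery tests certify
the estimation machinery under the model's own assumptions, not robustness
to the full messiness of empirical sessions. An `apply_exclusions` routine
implements the data-cleaning rules for empirical-style inputs (participant
excluded if reach-direction circular SD < 12° in any 20 consecutive trials;
trials with hand endpoint > 60° from the selected target dropped).

## Estimation

* **Reach model** — minimize the mean squared error between predicted and
  observed reach angles over *all* trials of a session (probes included;
  their predictions come from the decayed state), replaying the empirical
  choices and perturbations.
* **Selection models** — maximize the likelihood of the observed choices
  over choice trials, replaying updates from the empirical losses / signed
  errors / perturbations. The first choice trial contributes ln 3 by the
  deferred initialization. Log-probabilities are floored at 1e-300.
* Both use bounded Nelder–Mead (scipy) from multi-start initial values drawn
  uniformly within bounds from a given seed; the contract is "best of N
  seeded restarts", not a particular simplex implementation. Default
  bounds generously bracket the pooled estimates: a ∈ [0.5, 1], b ∈ [0, 1],
  l ∈ [0.05, 5], η ∈ [0, 1], λ ∈ [0.05, 5], β ∈ [0, 5]. Termination:
  xatol 1e-4, fatol 1e-6, at most 400 function evaluations per restart.
  Fitted parameters are clipped to bounds before being returned.

Objective replay runs over flat per-session arrays with the per-trial
kernel geometry precomputed (one objective evaluation ≈ 2–5 ms for a
424-trial session); tests assert the fast replay agrees with the
step-by-step model objects.

Two estimation caveats surfaced by the recovery experiments are worth
knowing. First, because the generator is noise-free, the true parameters
sit at an exactly-zero MSE minimum that an iterative optimizer can only
approach; "fitted objective ≤ objective at truth" is therefore checked at a
tolerance of 1e-6 deg² (an RMS prediction difference of one thousandth of a
degree). Second, the chance model occupies a ridge in the selection
parameter space — β = 0, or η = 0 with the value function frozen at its
constant initialization, produce identical (uniform) likelihoods — so
degenerate fits are validated by the fitted model's choice probabilities,
not by β alone.

## Evaluation metrics

* **Reach angle error**: wrap(y_t + α), signed by default; the absolute
  variant backs threshold rules. The "good learner" rule for Protocol 2
  requires a mean absolute error strictly below 20° over the last 50
  training trials.
* **Target selection error (TSE)**: |d(chosen, φ)| − min_i |d(option_i, φ)|,
  in [0, 120]; zero iff the closest option was chosen. Learning curves use
  10-trial-bin means with each session's first bin subtracted
  (*change in TSE*; negative = learning of φ). Model-predicted curves weight
  each option's TSE by the model's choice probabilities and can be aligned
  to the empirical first-bin baseline for overlay.
* **Preferred direction**: circular mean of the last 50 chosen directions.
* **Probabilistic fraction correct (PFC)**: geometric mean of the model's
  probabilities for the actually chosen targets over the last 50 choice
  trials; the uniform model scores exactly 1/3.
* **von Mises upper bound**: a von Mises distribution fit (ML; circular-mean
  μ, κ from the Best–Fisher A1-inverse approximation, capped at 1000 for
  degenerate samples) to the chooser's own last-50 choices, converted to
  per-trial choice probabilities by normalizing the density over the three
  offered options (computed in log space, so the capped-κ path cannot
  overflow). Because it is fit to the *marginal* chosen-direction
  distribution — flatter than the conditional preference when choices are
  concentrated, since options are constrained to a 120°-spaced triplet —
  it is a conservative reference for strongly concentrated choosers rather
  than a strict bound; it dominates the generating model's PFC in the
  weakly concentrated regime.
* **WLS goodness of fit**: per-participant differences (empirical − mean
  simulated) regressed on bias angle, weighted by the inverse variance of
  each participant's simulated runs (statsmodels WLS); a slope
  indistinguishable from zero means the simulations track the empirical
  trend, and p < 0.05 rejects the model.
* Circular mean and SD (sqrt(−2 ln R) in degrees) are computed from the
  resultant vector; an R of exactly zero yields an infinite SD flag rather
  than an exception, and an undefined circular mean raises. Both are
  cross-checked against scipy in the tests.

## Problem sizes and determinism

The test suite and the acceptance script use scaled simulation sizes chosen
to give stable statistics at desk scale: 20 sessions × 10 restarts for the
recovery regression (reach recovery is exact to ~1e-5; selection medians
η ≈ 0.016, λ ≈ 0.33, β ≈ 0.025 absolute error at 400 choice trials), and
200 runs per bias condition for the interaction contrast (mean change in
TSE ≈ −19° at α = 0° vs ≈ −1° at α = 40°, a difference more than an order
of magnitude larger than its standard error). All stochastic procedures
take explicit seeds; identical seeds give bit-identical sessions, fits and
CSV outputs.

## Known limitations

* Single-rate adaptation only; no fast/slow decomposition, savings or
  meta-learning.
* Exactly three options per choice trial; other choice rules (ε-greedy,
  UCB) are out of scope.
* The selection likelihood treats every feedback choice trial as updating;
  whether empirical pipelines should skip excluded trials inside the
  update sequence is a data-cleaning choice (here exclusions are applied
  before fitting).
* λ (selection kernel length-scale) is weakly identified at the pooled
  learning rate on 400-trial sessions: its likelihood is flat for small η,
  and recovery errors of ±0.3–0.5 are typical even when the fitted
  likelihood beats the truth.
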