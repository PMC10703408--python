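# reachsel

Joint modeling of visuomotor **reach adaptation** and reinforcement-based
**target selection** when movement errors contain both a constant bias and
direction-dependent noise.

## The problem

In a center-out reaching task, a visuomotor rotation is imposed between the
hand and the displayed cursor. On each trial the rotation is

    p_t = α + ε_t,    ε_t ~ U[−δ_t/6, +δ_t/6],

where α is a constant bias angle and the noise half-width grows linearly
(slope 1/6) with δ_t, the angular distance of the selected target from a
per-participant *least-noisy direction* φ. On each choice trial the agent
picks one of three targets spaced 120° at a random orientation, so it can
reduce noise by selecting targets near φ — but it can only discover φ by
exploring, and exploring means reaching in directions where the bias is not
yet compensated. The package simulates, fits and evaluates two interacting
learners that capture this trade-off:

**Reach adaptation** — a trial-by-trial state-space model with local
generalization. The learner keeps an estimate p̂_t(θ) of the perturbation per
target direction and aims to cancel it:

    y_t = −p̂_t(θ_t)
    d_t = p_t − p̂_t(θ_t)
    p̂_{t+1}(θ) = a·p̂_t(θ) + b·G(θ, θ_t)·d_t

with retention a, learning rate b, and the periodic kernel
G(θ,θ′) = exp(−2 sin²((θ−θ′)/2)/l²) localizing learning around the practiced
direction. On no-feedback probe trials the estimate only decays.

**Target selection** — softmax reinforcement learning over a per-direction
value function v(θ), P(choice=i) ∝ exp(−β·v(θ_i)), in three variants:

* `loss` — v = L̂, the expected loss (absolute feedback error), delta-rule
  updated with rate η and periodic kernel K (length-scale λ);
* `bias` — v = |R̂|, the expected *signed* error (tracks only the remaining
  bias);
* `noise` — v = S, a one-pass kernel-weighted running SD of the perturbation
  (tracks only the noise amplitude).

Simulated closed-loop sessions reproduce the headline phenomenon: with no
bias, agents learn to choose targets near φ; with a large bias, local
adaptation removes the error gradient that would drive exploration, and
learning of φ collapses.

## Worked example

`examples/02_fit_models.py` simulates one 424-trial session at the pooled
behavioral parameters (a=0.986, b=0.048, l=0.46, η=0.039, λ=0.80, β=0.15)
and refits both models:

```
reach model (MSE fit, deg^2):
  true:   a=0.986  b=0.048  l=0.460
  fitted: a=0.986  b=0.048  l=0.460   objective=3.69e-08
selection model (max-likelihood fit, nats):
  true:   eta=0.039  lam=0.800  beta=0.150   NLL at truth=353.85
  fitted: eta=0.044  lam=1.931  beta=0.263   NLL=350.90
```

The generator is noise-free given the replayed inputs, so the reach fit is
essentially exact (MSE ≈ 0 deg²); selection parameters carry the sampling
noise of 400 categorical choices, and the fitted likelihood slightly beats
the truth in-sample. `examples/03_bias_noise_interaction.py` shows the
bias–noise interaction on 50-run cohorts:

```
bias    0 deg: mean change in target selection error  -19.14 deg (SEM 2.30, n=50 runs)
bias   40 deg: mean change in target selection error   -1.81 deg (SEM 2.80, n=50 runs)
```

Negative values mean choices moved toward the least-noisy direction; the
40° bias almost abolishes that learning. The other examples cover single-
session summaries (`01`) and selection-model comparison by probabilistic
fraction correct with its von Mises upper bound (`04`).

## Command line

A thin CLI wraps the library for batch work:

```sh
reachsel simulate --config cohort.json --seed 1 --out runs/
reachsel fit-reach --sessions runs/sessions.csv --seed 2 --out fits/
reachsel fit-selection --sessions runs/sessions.csv --variant loss --seed 3 --out fits/
reachsel evaluate --sessions runs/sessions.csv --fits fits/ --out report/
reachsel recover --n 20 --seed 7 --out recovery.json
```

Sessions are stored as a plain CSV (one row per trial, angle columns with
`_deg` suffixes); configs and fit results are JSON.

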