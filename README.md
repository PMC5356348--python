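# reachdecomp

Decomposing trial-by-trial movement times from intensive arm-reach
training into **learning** and **fatigue**, with a nonlinear mixed-effects
model — and asking whether what was *learned* in one session predicts how
much better a person still is a month later.

## The problem

After stroke, people respond very differently to motor training. A
clinically useful signal would be something measurable *during* the first
training session that predicts long-term gains. Raw performance is a poor
candidate: in long, intensive sessions (600 reaches), performance often
worsens late in the session — from activity-dependent fatigability,
flagging attention, or motivation — even while learning is still
accumulating. Net in-session improvement therefore confounds two opposing
processes.

This package models the movement time (MT, ms) of participant *i* on the
*t*-th reach to target *k* (t = 1..120 per target, five targets) as

```
MT[i,t,k] = A_i · exp(−t / τ_i) + C_i · t + D_{i,k} + ε
```

- `A_i` (ms) — amplitude of the decaying exponential: how much MT
  improves through learning;
- `τ_i` (trials) — learning rate; the learning component halves every
  `τ ln 2` trials (the half-life);
- `C_i` (ms/trial) — the "fatigue" slope: linear worsening unrelated to
  learning;
- `D_{i,k}` (ms) — per-target asymptotic MT (targets differ in
  difficulty; left-affected subjects are mirrored onto the right before
  pooling);
- `ε ~ N(0, σ²)` — trial noise.

All eight parameters are mixed effects: a population mean (log scale for
`A`, `τ`) plus per-subject deviations with estimated diagonal covariance,
fitted jointly across subjects by SAEM (stochastic-approximation EM with
an MCMC E-step) and summarized per subject by empirical-Bayes posterior
modes. Derived metrics separate the two processes:

- **normalized learning** = `A(e^(−1/τ) − e^(−T/τ)) / MT_model(1)` — the
  exponential drop across training, relative to initial performance;
- **normalized performance change** — the *net* modelled change, i.e.
  learning minus accumulated fatigue `C(T−1)`, relative to initial
  performance.

The scientific payoff is the distinction between them: when fatigue is
present, normalized learning predicts the long-term change in MT
(Pre-test vs 1-month retention) while net performance change does not.

No trial-level data were published, so the package ships a first-class
synthetic-cohort generator calibrated to the published group statistics
(16 stroke subjects: median A = 279 ms, τ = 64 trials, C = 1.11 ms/trial,
D₅ = 432 ms, trial noise 76 ms; 10 controls: A = 128 ms, τ = 36 trials,
C = 0.12 ms/trial, noise 24 ms; dispersions calibrated to the published
IQRs). Every analysis stage runs end-to-end on these cohorts.

## Worked example

```python
import pandas as pd
from reachdecomp import (stroke_config, control_config, generate_cohort,
                         fit_nlme, FitConfig, metrics_frame, predict_long_term)

stroke = generate_cohort(stroke_config(16, seed=1))
control = generate_cohort(control_config(10, seed=2))
trials = pd.concat([stroke.trials, control.trials], ignore_index=True)

fit = fit_nlme(trials, FitConfig(seed=1))
print({g: round(v, 1) for g, v in fit.rmse.items()})
# {'control': 24.1, 'stroke': 74.9, 'overall': 60.6}
```

The fitted RMSE per group lands on the generating trial-noise floor
(24 / 76 ms): the model is capturing the structure, and what remains is
trial noise — about 10% of initial MT in both groups. Deriving per-subject
metrics and regressing long-term change on them:

```python
m = metrics_frame(fit.subjects, groups=[...])   # see analysis/04
res = predict_long_term(m_stroke, stroke.test_phases, "normalized_learning")
print(round(res.r2, 2), round(res.p_value, 3))
```

The `analysis/` directory holds the full study as numbered scripts
(simulate → extract MTs → fit → metrics → contrasts → long-term
prediction); each prints what it found and writes its tables under
`results/`. A `reachdecomp` CLI (`simulate`, `extract-mt`, `fit`,
`metrics`, `stats`, `run-all`, `demographics`) wraps the same library
functions for shell use.

Running the chain prints, among other things: the group contrast in the
fatigue slope (stroke median ≈ 9× control, Mann-Whitney p < 0.001), the
learning half-lives (stroke ≈ 44 trials of 120 — still learning at session
end; control ≈ 25 — plateaued), and the per-group regressions of long-term
change on the two training-derived predictors.

## Layout

```
src/reachdecomp/   model, synthetic cohorts, kinematics, SAEM fitting,
                   metrics, stats, io, pipeline, CLI
analysis/          numbered study scripts (thin drivers over the library)
tests/             unit, property and acceptance tests
docs/methods.md    modelling and estimation notes, assumptions, limits
```
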