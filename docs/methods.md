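# Methods notes

## The structural model

Movement time for subject *i*, per-target trial index *t* (1..T, T = 120)
and target *k* (1..5):

MT = A·exp(−t/τ) + C·t + D_k + ε,  ε ~ N(0, σ²).

The exponential models negatively accelerated learning; the linear term
models gradual worsening unrelated to learning (activity-dependent
fatigability, fatigue, attention); the five intercepts absorb systematic
target-difficulty differences. **`t` is the per-target occurrence index**,
not the global 1..600 session index — this matters because it sets the
scale of τ: τ = 64 means the learning component halves every ~44 reaches
*to the same target*. `t` starts at 1 (first reach), so "initial
performance" is the model value at t = 1 and "end of training" the value
at t = T. With C = 0 and A > 0 the curve is strictly decreasing; with
C > 0 it turns upward at t* = τ·ln(A/(Cτ)) — the U shape visible in
fatigued learners.

Derived per-subject quantities (targets aggregated by the arithmetic mean
of D_k; a per-target mode would only change the intercept):

- initial performance = model(1);
- amount of learning = A(e^(−1/τ) − e^(−T/τ));
- normalized learning = amount of learning / initial performance;
- final fatigue = C·T;
- normalized performance change = (model(1) − model(T)) / initial
  performance = normalized learning − C(T−1)/initial (exact identity,
  property-tested);
- half-life = τ·ln 2, reported rounded to whole trials.

## Estimation

The population model places the eight parameters on a transform scale —
log for A and τ (positivity; the fixed effect back-transforms to the
population *median*), identity for C (sign must stay free: controls can
speed up linearly) and D — with diagonal random-effect covariance.
Estimation is SAEM:

- **E-step.** Conditional on (A, τ) the model is linear in (C, D₁..D₅),
  so the linear block is integrated out analytically and (log A, log τ)
  is sampled by Metropolis against the collapsed likelihood — one
  independence kernel drawing from the current population distribution
  N(μ, Ω) (acceptance ratio reduces to the likelihood ratio) and one
  adaptive random-walk kernel per coordinate (target acceptance 0.30,
  adapted during burn-in only). (C, D) is then drawn exactly from its
  Gaussian conditional. This collapsing is essential, not cosmetic: the
  joint posterior has a long curved ridge (A↑, τ↑, C↑, D↓ trade off at
  nearly equal residual error; the linearized per-subject SE of A at the
  stroke operating point is ±450 ms), and componentwise random walks mix
  so slowly there that the estimate freezes far from the optimum.
- **SA/M-step.** Complete-data sufficient statistics are smoothed with
  step 1 for 300 burn-in iterations and 1/m^0.7 for 200 more; means,
  variances and residual variances are the closed-form maximizers.
  During burn-in, simulated annealing keeps σ² and Ω above geometrically
  decaying floors (start 2× the initialization, decay 0.97/iteration) so
  the chains stay mobile while the population moves.
- **Residual variance is estimated per group by default.** The two
  groups' trial noise differs threefold (76 vs 24 ms); a pooled variance
  understates the control group's likelihood precision ~6.6-fold and
  visibly over-shrinks control subjects toward the stroke-dominated
  population centre (their small fatigue slopes inflate several-fold).
  A pooled mode (`error_model="pooled"`) is retained.
- **Initialization** is two-stage: independent per-subject bounded
  nonlinear least squares (τ ∈ [0.5, 10T]; D ≥ 0, because without that
  bound the aliasing ridge admits degenerate A ≈ +3000 / D ≈ −3000
  solutions on weakly identified subjects), then cross-subject medians
  (location) and IQR-based variances (dispersion; a plain variance is
  blown up by the occasional ridge-riding fit) and pooled residual SD.
- **Empirical-Bayes** subject estimates are posterior modes, computed by
  the same profiling trick: closed-form (C, D) given (A, τ), 2-D
  Nelder-Mead over (log A, log τ), multi-started from the final chain
  state and the population means.
- τ is box-bounded to [0.5, 10T] throughout, preventing exponential/
  linear aliasing on flat learners. Everything is deterministic given
  the seed.

Verification: in the zero-noise, zero-dispersion limit the fixed effects
match an independent nonlinear-least-squares oracle to ~1e−7 relative;
on realistic cohorts the SAEM estimate's Laplace-approximate marginal
log-likelihood *exceeds* that of the generating population (it reaches
the MLE), and aligned per-subject empirical-Bayes estimates correlate
with the generating values at r ≈ 0.99 (log A), 0.95 (log τ), 0.89 (C).

### What recovery can and cannot achieve here

Group *medians* of the empirical-Bayes estimates recover the realized
cohort medians well under per-group fits (median absolute error over 10
seeds: A ≈ 5%, τ ≈ 3%, D₅ ≈ 2%, C ≈ 11%). Two structural limits are worth
stating plainly. (1) A joint fit of both groups under a single Gaussian
population is misspecified — the between-group spread inflates Ω,
weakening shrinkage exactly where the ridge needs it, and the stroke
medians drift upward along the ridge (tens of percent). (2) The control
group's fatigue slope (median 0.12 ms/trial, between-subject SD 0.067) is
small against its per-subject likelihood uncertainty, so its recovered
median tracks the estimated population mean, whose own sampling error at
n = 10 is ~±40% of 0.12: no estimator recovers that median to ±10%
reliably — empirical Bayes under the *oracle* prior (realized cohort
moments, true σ) already misses it in about half of seeds.

## The synthetic-data generator

The generator is the study-condition definition, not a convenience:

- cohorts of 16 "stroke" / 10 "control" subjects; 600-trial sessions in
  pseudo-random target order with exact 120-per-target counts and no
  immediate repeats (the next target is one of the other four);
- A, τ log-normal with median at the published group medians; C, D_k
  normal. Log-SDs are calibrated so the *quartile ratio* matches the
  published IQRs (the published quartiles are not log-symmetric about the
  published median — their geometric midpoint differs — so a median-
  anchored log-normal cannot match both endpoints; the ratio is what is
  preserved). Unprinted D₂..D₄ medians interpolate linearly between D₁
  and D₅, which were reported to increase monotonically;
- trial noise 76 ms (stroke) / 24 ms (control) — the residual scale a
  well-specified fit reports; MT floored at 50 ms; seeds explicit
  everywhere, same seed → identical tables;
- test phases: Pre1 mean = mean_k(A + D_k) + noise (naive state, no
  fatigue: tests are short and rested), 1-month mean = mean_k(D_k) +
  (1 − ρ)A + noise with retention fraction ρ = 0.8 and retention noise
  30 ms (stroke) / 15 ms (control). This generative link from training to
  retention is an invention of the generator (no such mechanism was
  published) and is the package's definition of "retention driven by the
  learning component".

What passing tests show — and don't. Because retention is driven by the
*full* amplitude A while normalized learning measures only its
in-session-expressed part, the heavy τ dispersion (log-SD 0.88) injects
variability shared by both training-derived predictors. Consequences:
the learning ↔ long-term-change regression has moderate R² even with
zero retention noise (~0.4, of the same order as the published real-data
R² = 0.37), rising above 0.95 only when τ and C are homogeneous; and
normalized learning beats normalized performance change in ~7 of 10
seeded cohorts rather than uniformly (the advantage is real on average;
with C = 0 the two predictors coincide exactly). Real data differ from
these cohorts in ways the generator does not emulate: no serial
correlation in ε, no within-session block structure or rest breaks, no
heteroscedasticity across targets, and a one-knob retention mechanism.

## Kinematics

MT extraction follows the standard chain: 5 Hz second-order Butterworth
(zero-phase, forward-backward — causal filtering would bias onsets late;
a causal option exists), planar speed from central differences, onset at
the first sample above 5% of peak speed, offset at the first sample at or
after the peak that is below 5% of peak *and* inside the 3-cm target disk
(searching from the peak onward prevents pre-movement jitter from
terminating the segment; requiring target entry prevents mid-path
hesitations from doing so). MT > 5 s is flagged as a timeout. Sensor rate
defaults to 120 Hz (typical of magnetic trackers; never published).

On noise-free minimum-jerk reaches the 5%-threshold span is
0.881132 × duration (exact root of s²(1−s)² = 0.05·0.0625), and the
extractor lands within one sample period of it *unfiltered*; the 5 Hz
filter broadens a 1-s profile by ~10 ms and a 0.3-s profile by ~45 ms,
which is a property of the published pipeline itself, not of this
implementation. Left-affected subjects' target indices are mirrored
k → 6−k (an involution fixing the centre target), with x mirrored about
the sagittal axis when trajectories are present.

## Statistics

Shapiro-Wilk screening is recorded but the group contrasts are
nonparametric throughout (median, 25–75% IQR, Mann-Whitney two-sided),
matching the analysis route of the source study; the age comparison is a
pooled-variance two-sided t-test (which reproduces the published p =
0.117; Welch gives 0.104). Mann-Whitney p-values are exact (full
enumeration) when n_x·n_y ≤ 400 and the pooled sample is tie-free,
normal-approximate with tie and continuity corrections otherwise; the
exact path is cross-checked against an independent exhaustive-enumeration
oracle in the tests. No multiple-testing correction is applied across the
eight parameter contrasts (none was applied originally); a Holm option
exists, default off. Associations are Pearson r with R² = r² and the
least-squares line; the long-term-change regressions support excluding
listed subjects, mirroring the with/without-outlier variants reported.

## Problem sizes and numerical choices

Defaults used by the tests and the acceptance script: cohorts at the
published sizes (16/10 × 600 trials), SAEM at 300 + 200 iterations with 2
MH sweeps (a 26-subject fit takes a few seconds; estimates are unchanged
at 500 + 500), recovery sweeps at 10 seeds, Mann-Whitney type-I
calibration at 300–500 null draws and power at 50 replicates. Floors:
ω² ≥ 1e−8, σ² ≥ 1e−6 (ms²), both far below any data-driven value and
relevant only in degenerate zero-noise configurations. Trial tables are
CSV with fixed schemas; ms / cm / trials units throughout.

## Known limitations

- Random-effect covariance is diagonal; correlations between A and D
  (plausible: more impaired subjects are slower *and* have more room to
  improve) are not modelled.
- The retention model is a synthetic-only construction; nothing here
  validates it against real retention data.
- Individual A, τ, C are weakly identified at stroke-level noise; only
  the population-regularized (empirical-Bayes) estimates, and groupwise
  summaries of them, are trustworthy. Single-subject NLS fits on such
  data should not be interpreted.
- The fitter estimates no standard errors for the fixed effects (none
  were published to compare against); the convergence trace is the
  diagnostic.
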