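# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite can show.

## Entropy estimation

GTE treats the fixation-category sequence as a first-order Markov chain over
k = 8 categories. Per current category x, the conditional next-category
distribution is estimated from the row of the forward-transition count
matrix and summarized by the Chao-Shen entropy: maximum-likelihood
probabilities are rescaled by the estimated sample coverage
C = 1 − S₁/N (S₁ = singleton transition types in the row, N = row total) and
each term is divided by the Horvitz–Thompson inclusion probability
la(x) = 1 − (1 − C·p_ML(x))^N. Design choices:

- **S₁ and N are per-row quantities** (the entropy is a property of each
  conditional distribution), not pooled over the matrix.
- **All-singleton rows** (S₁ = N) would give zero coverage; the standard
  implementation fix substitutes S₁ = N − 1.
- **Category self-transitions are counted by default**: consecutive
  fixations on two different buildings are a real building→building
  transition. `drop_self_transitions` exists for sensitivity analysis.
- **Stationary weights** π come from the principal left eigenvector of the
  row-normalized matrix restricted to observed categories. If the restricted
  chain leaks probability to unobserved categories, has a non-unique unit
  eigenvalue (reducible), or misses the 1e-10 residual tolerance, the
  empirical row-total marginal is used instead and the result is flagged
  (`pi_method="empirical"`). Unobserved rows get H = 0 and π = 0.
- **Normalization** divides by log₂ 8 = 3 bits. On very sparse rows the
  Chao-Shen correction can overshoot the theoretical maximum; normalized
  values are clipped to 1 and the clip logged at debug level.
- The estimator's sparse-sample bias is two-sided: concentrated rows at
  small N are estimated well, near-uniform rows at N ≈ k are still
  underestimated even after correction. Window-level (30-s) GTE values are
  therefore noisy (SD ≈ 0.1–0.27 in the generator's sessions); the
  hierarchical models, not the raw windows, carry the inference.

## Fixation classification

Angular velocity uses a translational correction: each gaze ray is projected
to its world end point (head position + hit distance · direction, with a
50 m default depth when nothing was hit), and the angle between consecutive
end points is measured from the midpoint head position, so walking past a
fixated point contributes no angular velocity. Classification thresholds are
data-driven per 10-s segment: median + 3·(1.4826·MAD). Two guards make the
rule total: velocities must also stay under an absolute ceiling
(100 deg/s — saccadic speed is never fixational, and the adaptive threshold
is undefined on zero-spread segments), and sub-threshold runs must last at
least 100 ms. Invalid-sample gaps under 75 ms (blinks) are bridged; longer
gaps split events. A fixation's object is the hit object with the longest
within-fixation hit time, ties broken lexicographically — deterministic by
construction. The threshold multiplier, segment length, minimum duration,
ceiling and blink bridge are all keyword parameters.

## Encounter windows

A fixation on an agent collider becomes an encounter onset iff no retained
encounter on the *same* agent occurred in the preceding 30 s (greedy
earliest-first scan; a `global` scope applies the refractory period across
all agents) and both the pre window [onset−30, onset) and post window
[onset, onset+30) lie inside the session. Edge-truncated windows are dropped
rather than shortened so window entropies stay comparable. The onset
fixation belongs to the post window (half-open convention). Windows with
fewer than 3 fixations (by midpoint) yield a flagged missing value.

## Hierarchical models

Both families are parameterized so the linear predictor is the log/logit of
the mean: Gamma(shape κ, rate κ/μ) and Beta(μφ, (1−μ)φ). Priors follow the
analysis plan: N(0,1) on slopes; Cauchy(0,2.5) on intercepts and group SDs
for Gamma models; Student-t(3,0,2.5) intercepts and group SDs and
Student-t(3,0,0.8) smooth SDs for Beta models; Gamma(0.01, 0.01) on κ and φ.
Random-intercept blocks are non-centered (b = σ·b_raw, b_raw ~ N(0,1)); the
encounter-index smooth is a centered cubic B-spline basis of dimension 5
treated as one such block under the smooth-SD prior. SDs and the auxiliary
parameter are sampled on the log scale with the Jacobian included.

Sampling is affine-invariant ensemble MCMC (emcee, differential-evolution
moves), initialised at a profiled posterior mode: fixed and random effects
are optimised by L-BFGS with analytic gradients while the group SDs are
frozen, each SD is then set to the empirical spread of its fitted effects
(raws rescaled to unit scale), and the cycle repeats once. A joint MAP is
deliberately avoided — in the non-centered parameterization it drifts along
the σ·b_raw ridge. Convergence is summarized by rank-normalized split R-hat
computed over 4 walker groups (interacting walkers are not independent
chains; grouping certifies between-group agreement and absence of drift)
with a 1.01 flag threshold; a flagged fit is returned with
`converged=False`, never silently. Sampler profiles: `test`
(~2.2 walkers/dimension, 1000 burn + 800 kept steps, thinned) for desk-scale
work, `reduced` for replicate studies, and `production` matching a full
analysis run of 4 chains × 6000 iterations with 3000 warmup. At desk-scale
profiles on small datasets the group-SD R-hats can sit just above 1.01; the
production profile resolves this.

Entropy responses are Smithson–Verkuilen transformed with n = the analysis
sample size before Beta fitting; pointing errors of exactly 0° are floored
at 0.1° (Gamma support) and the floor count logged. Posterior summaries
report means with highest-density intervals; dwell and pre/post effects
default to 89% HDIs, the rest to 95%, and both levels are available
everywhere. Back-transforms: percent change 100(e^β − 1) for log links,
odds ratios e^β and inverse-logit means for logit links.

## Mediation

Bayesian parametric g-computation with agent type as exposure (baseline
acontextual; congruent and incongruent each contrasted against it),
post-encounter GTE as the single mediator, and expected pointing error as
outcome. Per replication one mediator draw and one outcome draw are sampled
independently with replacement (seeded); plug-in mediator means are used —
the Beta precision affects dispersion, not the mean, so stochastic mediator
draws are unnecessary for point predictions. Context (residential/public) is
held coherent between the mediator and outcome pieces and averaged with
empirical trial weights. Dwell covariates are pinned at 0 on the z-scale and
random intercepts at 0 (average participant and location). Defaults: 4,000
replications (500 in quick runs); effects are summarized by posterior means
with 95% equal-tailed credible intervals. The additive and multiplicative
decompositions are exact per draw and are asserted, not just reported. No
exposure–mediator interaction is modelled.

## Synthetic-data generator

The generator is the package's stand-in for the study recordings; its
defaults are the study conditions of every test.

- **Fixation chain.** Condition-specific 8×8 row-stochastic matrices built
  from a shared anchor profile (most transitions land on buildings and
  background), a self-transition boost on environment categories, and a
  uniform mixing floor. Agent categories are sparse (0.003 anchor weight
  each — agents are 56 isolated objects in a 1 km² city) and get no
  self-boost: an agent is a single collider, and agent-row stickiness would
  pack artifactual rare-category runs into post windows. Incongruent
  placements use a slightly flatter matrix (long-run normalized GTE ≈ 0.62
  vs ≈ 0.53), mirroring the direction of the condition effect.
- **Durations.** Individual fixation durations are Gamma(2.0, 4.5)
  (mean ≈ 0.44 s, floored at 0.15 s) — free-viewing scale, so a 30-s window
  holds ~50 fixations; cumulative per-object dwell then lands in the
  seconds range. Saccades are symmetric triangular velocity profiles of
  30–80 ms with peaks at or above 200 deg/s; fixational jitter stays under
  4 deg/s; sampling is 90 Hz.
- **Encounters.** After any agent fixation the chain follows an
  *environment-flattened* matrix for 30 s (extended by new encounters):
  non-agent transition mass is mixed toward uniform at weight λ (default
  0.6) while agent probabilities stay untouched. Mixing the full matrix with
  uniform (the form of the standalone `simulate_encounter_shift` operation)
  would make agents 3/8-likely post-encounter and the flattened state would
  re-trigger indefinitely. With the defaults the paired post-minus-pre
  window GTE contrast is ≈ +0.05 and vanishes at λ = 0.
- **Regression datasets.** Each model has a generator drawing from exactly
  the likelihood the model fits, at generative coefficients whose magnitudes
  match the effects the analysis is designed to detect (e.g. dwell
  interaction 0.41, pre/post logit shift 0.38, GTE slope −0.31 on log
  error). Entropy-model Beta precisions default to φ = 8, calibrated to the
  per-window GTE spread the package's own gaze pipeline produces
  (SD ≈ 0.1–0.15); group SDs (0.19–0.33) reflect modest participant and
  location heterogeneity. The pointing-trial generator draws the GTE
  covariate from the mediator model so the mediation pathway present in the
  data matches the coefficients used as ground truth.

**What the generator does not emulate:** scene geometry and visibility
(categories are sampled, not ray-traced), smooth pursuit, blinks beyond
validity gaps, eye-tracker noise spectra and calibration drift, session
fatigue, or any dependence of pointing error on actual spatial layout.
Passing tests therefore demonstrate that the estimators and models recover
the structure they assume, at the noise levels chosen — not that the
assumptions hold for any particular real recording.

## Problem sizes

Round-trip and classifier checks use single 300–600-s sessions. Recovery
fits use 1,200–6,000 rows with 16–32 participants at the `test` profile;
interval-calibration runs 50 replicates per model at ~240 rows with 8
participants at the `reduced` profile, counting coverage over every fixed
coefficient. Transition-matrix round-trip fidelity (max-entry error ≤ 0.03
at 5,000 fixations) is assessed with λ = 0 and a concentrated cyclic
chain that visits every row evenly with low per-cell variance: under the
realistic defaults agent rows receive ~25 visits per 5,000 fixations, where
no estimator could meet that tolerance; a diagonal-heavy chain conflates
same-object repeats (merged into single fixations) with category
self-transitions; and with flattening on the realized process is a pre/post
mixture rather than a single matrix.

## Known limitations

- Ensemble MCMC at desk-scale budgets yields grouped-walker R-hat, not the
  multi-chain HMC diagnostic a production Stan run would give; the `paper`
  profile narrows the gap but single-mode agreement is still the main
  evidence of convergence.
- The Chao-Shen estimator's residual small-sample bias means window-level
  GTE is best treated as a noisy index; between-condition contrasts are
  reliable, absolute window values are not.
- The mediator–trial linkage uses generated pointing trials keyed to
  participants and locations; linking real trials to specific encounters
  (e.g. averaging gte_post over encounters with the agent at the trial's
  target) is supported by the data model but not exercised against real
  geometry.
- KDE mode and FWHM depend on the bandwidth rule (Silverman by default);
  the bandwidth used is always reported alongside the summaries.
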