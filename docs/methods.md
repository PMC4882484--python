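# Methods

## Stimulus geometry

An RF pattern is `r(θ) = r_mean·(1 + A·m(θ))` with modulator
`m(θ) = T_k(ωθ + φ) / max|T_k|`, where `T_k` is the triangle-wave Fourier
series truncated after `k` harmonics above the fundamental:
`T_k(x) = sin x + Σ_{j=1..k} (−1)^j sin((2j+1)x)/(2j+1)²`. With `k = 0`
the modulator is exactly the fundamental sinusoid (no rescaling is applied,
so the k = 0 path is bit-identical to `sin(ωθ + φ)`); with `k = 30` it
correlates > 0.999 with an ideal triangle wave.

**Peak normalisation.** The truncated series is rescaled to unit peak
(located by a dense grid plus bounded scalar refinement, cached per `k`) so
that the amplitude factor `A` always equals the maximum fractional radial
deviation. Without this, higher spikiness would also change the effective
amplitude and the two factors would no longer be independent manipulations.
The rescaling can be disabled (`normalize=False`).

**Phases.** The factorial stimuli use φ = 0. The composite presets place
the aligned peaks at θ = π/2 (top of the figure): component phases are
`φ_i = ±π/2 − ω_i·π/2 (mod 2π)`, with the minus sign (trough alignment)
applied to the 2nd and 4th components of the "rounded" preset. The five
components have frequencies (7, 14, 21, 28, 35) and amplitudes
(0.4, 0.2, 0.1, 0.05, 0.025), so the aligned-peak radii are 1.775·r_mean
(angular) and 1.275·r_mean (rounded).

**Sampling and lobe counting.** Contours are sampled on 4096 uniform
angles over [0, 2π) (the first vertex repeated to close the polygon).
Lobes are strict circular local maxima of the radius sequence after
collapsing plateaus; radii are quantised at a relative tolerance of 1e-9
first, so floating-point jitter on an exact circle does not create
spurious maxima. Renderers use mathematical (y-up) coordinates internally
and flip to image coordinates only at export; PNG encoding options are
fixed so identical inputs give identical bytes.

## Generative respondent model

Responses are Bernoulli draws from
`logit P(Kiki) = β₀ + b_i [+ c_g] + (β + Δ·1[US]) · x`, with participant
intercepts `b_i ~ N(0, σ²_id)` and, in two-group shared-coefficient mode
with `σ_group > 0`, one nationality offset per group. Taiwan is the Δ
baseline: the published Δ signs (positive amplitude, negative spikiness)
then read directly as US-minus-Taiwan differences.

**Predictor coding.** The default coding is frequency raw (4–9),
amplitude × 100 (10–40), spikiness raw (0, 1, 30). The published slope
magnitudes only produce response probabilities spanning chance under this
unit system (US logits range ≈ −2.4 to +2.7 over the design); an identity
coding is selectable.

**σ_id default 1.0 logits.** The original study did not report the
random-intercept variance. One logit of between-subject spread is a
typical magnitude for binary psychophysical judgements (±2σ subjects move
a 50% condition to roughly 12–88%); it is configurable everywhere.

**What the simulator does not emulate.** Sound-order effects (the BK/KB
counterbalancing is generated but carries no coefficient), response
times, demographic covariates, learning/order effects within a session,
and any lapse/guessing process. Passing recovery tests therefore show
that the analysis chain is consistent for data that truly follow the
logistic random-intercept law — not that real judgements do.

## Agreement maps

Per condition, pooled responses are tested against chance with the 1-df
Pearson goodness-of-fit statistic `(2k − n)²/n` (no continuity
correction), α = 0.05, saturation bands at 0.05/0.01/0.001, no
multiple-testing correction — each cell is reported on its own, and the
pooling deliberately ignores within-participant correlation (the mixed
model is the correlation-aware analysis). An exact binomial test is
available; the two tests can order counts near the α boundary differently
(e.g. n = 300, k = 133: Pearson p = 0.0497 vs exact p = 0.0566), which is
inherent to the tests, not a numerical issue.

## Mixed-logit estimation

The marginal likelihood integrates the random intercepts numerically.

- **One random factor (participants):** the likelihood factorises over
  subjects; each 1-D integral uses adaptive Gauss–Hermite quadrature
  centred at the subject's penalised-likelihood mode (damped Newton with
  per-subject step halving) and scaled by its curvature. Default 15
  nodes; 1 node is exactly the Laplace approximation. With 15 nodes the
  log-likelihood matches brute-force trapezoid integration to ~1e-8 on
  toy instances, and the 1-node path reproduces lme4's Laplace fit
  (coefficients, σ and logLik to ~1e-4 on identical data). Adaptive
  quadrature was preferred over plain Laplace as the default because it
  is exact ML to quadrature precision at negligible extra cost in one
  dimension.
- **Two random factors (participants + nationality):** a joint Laplace
  approximation at the joint mode (as lme4 itself forces with more than
  one random term). The Hessian over (b, c) is arrowhead-structured —
  subjects are conditionally independent given their group — so the
  Newton solve and log-determinant use a diagonal Schur complement and
  cost O(S + G).

**Optimisation.** L-BFGS-B over (β, σ_id[, σ_group]) with σ bounded below
(σ_group may sit exactly on the 0 boundary; the factor then drops out of
the likelihood, which is continuous there). Starting values come from a
plain IRLS logistic fit with σ_id = 1. Non-convergence is flagged on the
result, never silent. With only two nationality levels σ_group is weakly
identified and routinely collapses to the boundary; the parameter still
counts toward the ladder's df (5/9/8), matching the published accounting.

**Standard errors.** Hessian SEs invert the central-difference Hessian of
the marginal log-likelihood at the optimum (boundary-stuck parameters are
excluded and get NaN). Parametric-bootstrap SEs (default 200 replicates;
the original analysis used 10⁶, far beyond desk scale) simulate from the
fitted model over the same design, refit, and take the SD of replicate
estimates, dropping and counting non-converged replicates (> 10% drops
warns). Wald CIs use exactly ±1.96·SE, matching the published interval
arithmetic rather than a refined normal quantile.

## Model ladder

Model 1: intercept + three slopes + participant intercepts (5
parameters). Model 2 adds ΔFrequency, ΔAmplitude, ΔSpikiness
(coded-predictor × US-indicator columns) and a nationality intercept (9).
Model 3 is Model 2 without ΔFrequency (8). LRTs compare deviances against
a χ² with df equal to the parameter-count difference, with no boundary
correction for the variance component — the naive reference matches the
published arithmetic. Tiny negative LR statistics (< 1e-6) are clamped to
zero; larger ones warn about a non-converged fit.

## Problem sizes in tests and the acceptance script

Parameter-recovery runs use the published design: 20 replicates of 150
(US) or 88 (TW) participants × 72 trials, and 20 two-group replicates
(238 × 72 rows) for the Model 3 ΔAmplitude recovery. Calibration-style
checks (Wald coverage, type-I error of ΔFrequency, LRT power) use reduced
group sizes (20–75 participants per group) with thresholds adjusted for
the reduced noncentrality where relevant; these sizes are the package's
own choices for desk-scale validation studies. Replicate seeds derive
deterministically from a single base seed.

## Known limitations

- The nationality "random intercept" has two levels; its variance is not
  meaningfully estimable and the implementation lets it sit on the zero
  boundary rather than inventing structure.
- The two-factor likelihood is Laplace-only; its absolute log-likelihood
  carries the usual Laplace bias (irrelevant to the ladder's deviance
  *differences*, which are what the LRTs consume, but visible when
  comparing Model 1 — quadrature — against Models 2–3 on data where
  σ_group leaves the boundary).
- Agreement-map tests pool across participants by design and inherit the
  anticonservatism that pooling implies under positive within-subject
  correlation.
- The renderer draws outlines only; it does not reproduce display-level
  properties (anti-aliasing, size calibration) of any particular
  experimental setup.
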