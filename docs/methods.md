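# Methods

## Model

The unit of inference is a placebo **study arm**. The observed quantity
at week `t` is the arm's mean change from baseline in the 11-item
ADAS-cog (0–70 points, higher = worse). The structural model is

    S(t) = α·t + Pbo(t),        Pbo(t) = β·t/(ET50 + t)

with α the disease-progression rate (points/week), β the asymptotic
placebo extent (points, typically negative) and ET50 the placebo
half-time (weeks). Alternative placebo-effect forms are available for
structural comparison: sigmoid Emax `β·t^h/(ET50^h + t^h)`,
exponential onset `β·(1 − e^(−k_on·t))`, and an inverse Bateman form
`β·(e^(−k_off·t) − e^(−k_on·t))/c` with `c` chosen so that β is the
extremum of the curve. The last two are parameterised by rate
constants that the data often cannot identify on short designs; the
inverse Bateman form failing to converge on designs dominated by
≤12-week trials is expected behaviour, not a defect.

Between-study heterogeneity is proportional: `α_i = α_typ·f_i·(1+η_α)`
and `β_i = β_typ·(1+η_β)`, where `f_i` is the product of covariate
factors (below) and `(η_α, η_β) ~ N(0, Ω)` with SDs `ω_α, ω_β` and
correlation ρ. The proportional (rather than log-normal) form is
deliberate: study-level slopes and placebo extents can legitimately be
negative (improving cohorts, nocebo responses). ET50 carries no
random effect — in study-level data its inter-study variability is
essentially unidentifiable (empirical-Bayes shrinkage near 100%), so
it is fixed at zero.

The residual on an arm mean of `n` subjects is `ε/√n`, `ε ~ N(0, δ²)`:
δ is interpretable as a per-subject residual SD, and arm means are
weighted by their reporting precision.

### Covariate functions

All covariate factors equal exactly 1 at the reference value:

- power: `(x/x_ref)^θ`
- linear: `1 + θ·(x/x_ref − 1)` (the factor-of-one-at-reference
  rendering of a linear effect; the exact linear form is a convention
  choice)
- inverse-U: `((x/x_ref)·(70−x)/(70−x_ref))^θ` — captures the bounded
  scale: for θ > 0 the factor peaks at exactly 70/2 = 35 points
  regardless of θ (the kernel `x·(70−x)` is symmetric about 35), so
  mid-scale cohorts progress fastest
- indicator: `1 + θ·(x − x_ref)` for 0/1 dichotomous covariates

The scale ceiling (70) is a named, overridable constant. The final
covariate model places the inverse-U baseline-severity effect and a
power age effect on α; references are the study-level medians
(ADAS-cog 24.5, age 73.5 years).

## Estimation

With ET50 fixed across studies the model is **linear in η**, so each
study's marginal likelihood is Gaussian and the Laplace approximation
(expansion about the conditional mode of η) is exact; the conditional
mode solves a 2×2 linear system. With a purely additive residual the
FOCE-I "interaction" term vanishes, so the FOCE-type objective
coincides with Laplace; the package also evaluates the marginalised
Gaussian form `Σ_i = X_i Ω X_iᵀ + D_i` by batched Cholesky as an
algebraically independent route, and adaptive Gauss–Hermite quadrature
(≥9 nodes/dimension, product grid centred at the conditional mode) as
a slow reference oracle. Tests require all three to agree.

The OFV is the full −2 log marginal likelihood including 2π constants
(some estimation tools drop them); only OFV differences are
interpreted, so the convention is harmless and is stated here once.

Optimisation is unconstrained L-BFGS-B on transformed parameters: log
for ET50, hill, rate constants, ω's and δ; atanh for ρ; identity for
α, β and the θ's. Analytic gradients of the marginal Gaussian
objective are used for the Emax, sigmoid-Emax and exponential forms
(verified against central finite differences to ~1e-8); the inverse
Bateman form falls back to finite differences. Defaults: relative
function tolerance 1e-12, gradient tolerance 1e-7, 500 iterations,
best of 3 multi-starts whose jitter multiplies natural values by up to
×/÷3 (seeded, so fits are deterministic given data, spec, starts and
seed). Starting values are data-driven: (α, β) from a √n-weighted
linear regression of the observations on `[t, t/(8+t)]`, ET50 = 8
weeks, ω = (0.2, 0.5), ρ = −0.3, δ from the regression residual scale.

Standard errors come from the finite-difference Hessian of the
objective at the optimum, back-transformed by the delta method
(numerically, via the Jacobian of the transformed→natural map);
RSE% = 100·SE/|estimate|. ρ is reported as the derived Pearson
correlation without an SE by default. A singular Hessian yields
estimates with SEs marked unavailable rather than a failure.

Empirical-Bayes estimates are the per-study conditional modes of η;
their SEs come from the conditional Hessian, mapped to `(α_i, β_i)` by
the delta method. Shrinkage is `1 − SD(η̂)/ω` per effect. Structural
model selection fits each candidate placebo form and ranks converged
fits by AIC = OFV + 2·(number of estimated parameters).

## Covariate screening

Stepwise: forward inclusion accepts the candidate with the largest OFV
drop strictly greater than 3.84 (χ², P < 0.05, df = 1), repeated to
exhaustion with re-ranking each round; backward elimination then
removes any covariate whose deletion raises the OFV by ≤ 6.64
(P < 0.01). Candidates observed in fewer than 70% of studies never
enter. A candidate may carry several functional forms (baseline
severity: power and inverse-U); the best form's drop is the
candidate's score and each inclusion costs one degree of freedom.
Ties within 1e-6 break by candidate order. Refits warm-start from the
incumbent optimum; the final model is refitted cold as a cross-check.
The audit trail records every fit's OFV and every decision.

Note a screening limitation quantified during development: over the
severity range the generator samples (few cohorts above the ADAS-35
curvature point), the power and inverse-U forms of the baseline-ADAS
effect fit almost equally well, so which form wins the
within-candidate comparison on synthetic data is effectively a coin
flip even though the covariate itself is selected nearly always.

## Evaluation

The bootstrap resamples **studies** with replacement to the original
study count (the model's exchangeable unit) and refits each replicate,
warm-started at the original estimates with looser optimiser
tolerances (replicate error ≪ percentile Monte-Carlo error); failures
are reported in the denominator and >50% failures flag the result
unreliable. The VPC simulates replicate datasets on the observed
design (same studies, times, n, covariates) from the fitted
parameters, bins observations by exact nominal visit week (aggregate
data cluster on protocol visits; width-based binning is available) and
compares observed 2.5/50/97.5% quantiles to their simulated 95%
bands. Diagnostics report population predictions (η = 0), individual
predictions (η = η̂), `WRES = (y − PRED)·√n/δ̂`, and CWRES from the
first-order conditional expansion — exact here, again by linearity in η.

## Subgroup analysis

Two steps. (1) Per-study empirical-Bayes `(α_i, β_i)` with conditional
SEs; each `α_i` and its SE are divided by the study's covariate factor,
rescaling it to the reference profile (age 73.5, ADAS-cog 24.5) so
strata with different case-mix are comparable ("inverse calculation" of
the covariate model; β carries no covariates and passes through).
(2) DerSimonian–Laird random-effects pooling of a single mean within
each stratum (publication era, add-on design, six-region geography);
α is annualised ×52. Typical time-course curves use the pooled
stratum (α, β) with the global ET50; their 95% bands propagate only
the pooled means' SEs by parametric draws (between-study τ² is
excluded by default — the bands describe the typical curve, not a new
study's curve; a flag could widen them).

Shrinkage attenuates stratum contrasts in this two-step approach:
a generator-side 7% regional slowdown on α is reduced to ~2–3% in the
corrected EBE means when the stratum has only a handful of small
studies. Sensitivity tests therefore aggregate across replicates
rather than requiring per-replicate ordering.

## Synthetic data generator

The generator emulates a 140-trial aggregate literature landscape and
is the package's test bed: per-study baseline ADAS-cog ~ truncated
Normal(24.5, 5²) on [13.1, 39.3]; age ~ truncated Normal(73.5, 4²) on
[58.0, 81.7]; arm size log-normal (median 102, log-SD 0.8) truncated
to [11, 746]; visit schedules drawn from a stylised pool of 2–6 visit
designs up to 104 weeks (the joint distribution of real protocol
schedules is unknown; this pool is a stand-in); regions with
frequencies (56, 56, 15, 5, 5, 3)/140; publication era pre-2008 with
probability 64/140 and add-on designs only post-2008 (27/76). The
truncated-normal shapes and the log-normal arm-size law are
distributional choices constrained only by the published medians and
ranges. Default true parameters are the final-model estimates (α =
0.112, β = −1.87, ET50 = 7.99, θ_ADAS = 1.53, θ_age = −2.17, ω =
(0.148, 0.725), ρ = −0.717, δ = 5.64). One master seed spawns a
substream per study, so extending the study count never perturbs
earlier studies. An optional per-region α multiplier exists solely to
probe subgroup sensitivity; it is outside the estimation model.

What the generator does **not** emulate: dropout and attrition
(per-visit n is constant within an arm), digitisation error from
figure extraction, reporting/publication bias, schedule–region
correlations (e.g. short East-Asian trials), active arms, and
patient-level variability. Passing recovery and calibration tests
therefore shows the estimator is correct under the model's own
assumptions, not that the model is correct for any given literature.

## Problem sizes used by the test suite

Scaled to keep the default run quick while preserving the statistical
meaning of each check: parameter-recovery calibration uses 40
replicate 140-study sets; the Laplace-vs-quadrature check uses 100
randomised 5-study instances; screening calibration uses 20 effect and
20 null 140-study replicates; bootstrap coverage uses 20 outer
replicates of 40-study sets at B = 100 (percentile intervals at B =
100 are slightly noisy, which the 85–99% coverage band accommodates);
the VPC check uses 400 simulations. Stochastic acceptance tolerances
are ~2 Wald SEs, rendered as 2.5 SEs so a joint four-parameter check
at nominal calibration is not failed by ordinary sampling noise, with
a 50%-relative floor for the weakly identified ET50.

## Known limitations

- Aggregate-level inference: covariate effects are ecological
  (study-mean age, not patient age) and need not equal patient-level
  effects.
- The inverse-U severity effect extrapolates poorly above the observed
  severity range (few cohorts above ~40 points).
- ET50 is weakly identified on protocol-visit schedules (RSE ≈ 20–50%
  depending on the design mix); simulation-and-refit spreads of ±50%
  are normal.
- ρ estimates at moderate study counts often drift toward −1 when ω_α
  is small; the atanh parameterisation keeps the optimiser stable but
  the correlation should be read with its weak identifiability in
  mind.
- The two-step subgroup analysis inherits EBE shrinkage, biasing
  stratum contrasts toward zero for small strata (see above).
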