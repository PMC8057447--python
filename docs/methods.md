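# Methods

## Model

Longitudinal submodel. Global cognitive z-scores `y_ij` for subject `i` at
years-since-enrollment `t_ij` follow a linear mixed model whose mean couples
baseline covariates `x_i`, time, covariate-by-time interactions, and the
time-dependent exposure term `u_ij = max(0, t_ij − s_i)`, where `s_i` is the
time of the first post-enrollment surgery with general anesthesia (`u ≡ 0`
for never-exposed subjects). Time is continuous and never binned. The
exposure effect accrues strictly after `s` (half-open convention: a visit at
exactly `s` carries `u = 0`). Random effects are subject-level intercept,
slope and post-exposure slope change, `b_i = (b0, b1, b2) ~ N(0, G)` with
unstructured `G`; residuals are i.i.d. Gaussian with SD `σ`.

Dropout submodel. The composite dropout endpoint (dementia diagnosis or
death) follows a proportional-hazards model with a piecewise-constant
baseline hazard on knots at event-time quantiles (default 5 pieces),
covariate log-hazard effects `γ`, and the shared random effects as
time-fixed covariates with association coefficients `α = (α0, α1, α2)`. The
piecewise-constant baseline gives the cumulative hazard in closed form, so
the complete-data joint likelihood is exact — no numerical integration
anywhere in the likelihood itself. A spline baseline, current-value or
slope-value association structures, competing-risks and multistate
extensions are deliberately out of scope.

Under MAR dropout the LMM alone, fitted by maximum likelihood, is valid;
under MNAR dropout (α ≠ 0) it attenuates the exposure coefficient toward
zero because fast post-exposure decliners leave the risk set early. The
shared parameter model corrects this by letting the dropout times inform
the random-effect posteriors.

## Estimation

LMM: maximum likelihood (ML, matching the analysis the package mirrors;
REML deliberately not the default) on the profiled Gaussian marginal
likelihood. `β` and `σ²` are profiled out in closed form; the optimizer
works on the relative covariance `G/σ²` through a log-Cholesky
parameterization (positive semidefiniteness never binds), with two fixed
deterministic starts (BFGS then Nelder-Mead polish). Subjects are batched by
visit count so each objective evaluation is a handful of batched Cholesky
factorizations. Wald covariance for `β`; AIC = −2ℓ + 2p with p counting
fixed effects, the Cholesky parameters and `σ`. Agreement with an
independent mixed-model implementation is ~1e-6 in log-likelihood on test
cohorts.

Joint model: Metropolis-within-Gibbs.

* conjugate updates — `β` (Gaussian), `σ²` (inverse-gamma), `G`
  (inverse-Wishart given the current `b`), and the baseline rates (gamma,
  from the piecewise-exponential structure);
* adaptive random-walk blocks for `γ` and the free components of `α`
  (association structures: none / intercept / intercept+slope / full),
  scale-adapted during burn-in toward 0.3 acceptance (0.23–0.44 band), with
  the proposal covariance taken from the accumulating burn-in draws; each
  block is repeated 5 times per sweep, which is cheap and mixes the slowest
  parameters;
* random effects — independence Metropolis from the longitudinal full
  conditional `N(m_i, P_i⁻¹)`, so the acceptance ratio reduces to the
  survival likelihood ratio; updates are vectorized across subjects
  (acceptance ≈ 0.85–0.9 in practice).

Priors ("diffuse, in the reference-software spirit", each a package choice
since the mirrored analysis names no numbers): `β, γ ~ N(0, 100²)`;
`σ² ~ IG(0.01, 0.01)` — conjugate rather than half-Cauchy, keeping the
residual-variance update exact; `G ~ IW(df = q+2, scale = 0.01·I)`;
`α ~ N(0, 10²)` — the association coefficients multiply random effects with
SDs between 0.05 and 0.8 z-score units, so plausible magnitudes are O(1–10)
and SD 10 is diffuse on that scale while damping excursions of the weakly
identified exposure-slope association. Survival covariates are centered
internally (absorbed into the baseline rates) for mixing.

Two chains by default; convergence is flagged by split-chain potential scale
reduction with threshold 1.05 (cross-checked against arviz). Everything is
reproducible under a single seed, with per-chain and per-pipeline-stage
streams derived by a counter-based scheme so stages can be rerun
independently.

Verification oracle. The marginal likelihood (random effects integrated
out) is computed by adaptive Gauss–Hermite quadrature centered at the
per-subject posterior mode of `b` (damped Newton with analytic gradient and
Hessian, batched over subjects) with curvature-matched scaling. On
linear-Gaussian cases it reproduces the closed-form marginal exactly; on
1-D toys it matches dense trapezoid integration to 1e-6; node counts 5 vs 15
agree to ~1e-6 on smooth cases. DIC uses this *marginalized* deviance
(DIC = D̄ + pD, pD = D̄ − D(θ̄)); DIC is parameterization dependent and the
conditional-on-b variant would differ.

## Dropout endpoint rules

`define_dropout` is total and idempotent: dementia diagnosis → event at the
diagnosis date; else death within 18 months (window configurable) of the
last study visit → event at death; otherwise censored at
`min(last visit + margin, administrative end)` with margin 0 by default —
a death beyond the window is treated as dropout for other reasons first
(assumed MAR), and the censoring time for such subjects is the last visit
because no later alive date is modeled. Follow-up is summarized by reverse
Kaplan–Meier (product-limit with the censoring indicator flipped),
implemented directly and cross-checked against lifelines. The
piecewise-exponential PH fit used to initialize the joint model profiles the
rates in closed form (events over weighted person-time) and agrees with a
Cox partial-likelihood fit within 0.02 on `γ` when knots are dense.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the cohort anatomy the analysis assumes:
covariates drawn from configured marginals (age 70 + gamma excess matching
median 78–79 and IQR ≈ [74, 83]; 49% female, 16% MCI, 27% APOE ε4, 36%
midlife hypertension, 43% dyslipidemia, and so on — marginals only,
independence by default since only marginals are reported for the real
cohort); visits at 0 plus i.i.d. gamma gaps (shape 8.1723, scale 0.16578:
median 1.3 years, 1st/99th percentiles ≈ 0.5/2.7), truncated at a
staggered-entry administrative censoring time (study end 10.2 years,
enrollment window 5.2, so per-subject censoring ~ U(5.0, 10.2)); a single
first post-enrollment exposure from an exponential clock (0.058/year,
recorded only if it precedes end of follow-up; repeat surgeries out of
scope); z-scores from the longitudinal model; and dropout by
inverse-transform sampling of the piecewise-constant proportional hazard,
labelled dementia with probability 0.389 else death, independently of the
event time. Under `regime="MAR"` the generator forces `α ≡ 0`; under
`"MCAR"` also `γ ≡ 0`.

Default truth (stored in `cogjoint/data/default_config.yaml`, not in code):
the exposure slope change is −0.081 z/year — the shared-parameter estimate
of the reanalysis the package mirrors — with reference slope −0.03 and
interaction terms giving a marginal pre-exposure slope near −0.05;
`G = diag-ish(0.55, 0.006, 0.025)` with a small negative intercept-slope
covariance; `σ = 0.30`; hazard rates (0.0131, 0.0179, 0.0221, 0.0262) on
knots (0, 2, 4, 6); `γ` = (0.70 age/decade, −0.25 female, 0.30 APOE ε4,
0.70 MCI); `α = (−0.5, −10, −5)`.

Two calibration notes. First, the association vector and `G₂₂` were chosen
together so that the MAR mixed model's attenuation of the exposure effect
matches the ~20–25% the MNAR reanalysis reports; the same attenuation is
achievable with a larger `|α₂|` acting on a smaller exposure-slope variance,
but that corner of the parameter space is poorly identified (an `α₂`–`G₂₂`
likelihood ridge along which chains mix slowly and the posterior mean
under-corrects), so the defaults use the better-identified combination of a
moderate `α₂ = −5` with `G₂₂ = 0.025`. Second, the generator produces ~6
visits per subject at the default sizes versus the 4 of the real cohort: the
difference is attendance dropout for reasons other than death or dementia
(relocation and the like), which is assumed MAR and deliberately not
simulated. Passing tests therefore demonstrate correct behaviour under the
modelled dropout mechanism, not robustness to visit-process misspecification
or to covariate dependence structures the marginals do not determine.

## Numerical and design choices

* Exposure boundary: `u = max(0, t − s)`, effect strictly after `s`.
* Covariate coding is fixed in a data dictionary (`coding.py`): age linear
  per decade over 80, education a 4-level ordinal factor with `<12 years`
  reference, marital/smoking dummies with `married`/`never` references.
  Both are assumptions, not facts about the mirrored analysis. The default
  model covariate set is (age, sex, APOE ε4, MCI); the full adjustment list
  is available as `FULL_MODEL_COVARIATES`.
* Random-structure selection minimizes AIC, ties broken toward fewer
  parameters; non-convergent candidates are excluded with a warning.
* The joint model *refuses* longitudinal records after a dementia diagnosis
  rather than dropping them, making the exclusion an explicit pipeline
  stage with a reported removal count.
* The dementia-only sensitivity fit converts death dropouts to censorings at
  their event time (dementia MNAR, death MAR). Under the default generator
  death dropout is also informative, so this fit is mildly misspecified by
  construction and recovers an estimate between the MAR LMM and the full
  joint model — the same qualitative ordering the mirrored analysis reports.
* The relative MNAR-vs-MAR contrast is reported sign-aware in magnitude:
  `(|joint| − |lmm|)/|lmm|`, positive when the joint estimate is further
  from zero on the same side.
* Degenerate inputs: zero baseline hazard under MNAR is rejected at config
  validation (no events, association unidentifiable); a cohort with no
  dropout events skips the joint fit with an explicit notice; all-censored
  data make the reverse-KM median "not reached" (NaN); empty hazard pieces
  estimate their rate at the boundary 0 with a warning.

## Problem sizes used in the shipped studies

The replicated recovery studies run at n = 500–600 subjects with 3–8
replicates and 3000–4000 MCMC iterations per chain (two chains), sizes at
which the Monte Carlo standard error of a replicate-mean slope change is
0.004–0.01 z/year; the acceptance script uses n = 600 with 8/6/4 replicates
for the LMM / joint / dementia-only studies. These are the package's own
desk-scale choices; the same code runs unchanged at the full ~1950-subject
scale.

## Known limitations

* The sampler is a plain adaptive Metropolis-within-Gibbs; posteriors with
  very weakly identified association components (tiny event counts, or the
  ridge corner described above) mix slowly and are flagged by the split-Rhat
  diagnostic rather than repaired.
* Only shared-random-effect association structures are implemented.
* Cause labels are independent of the event time by construction, so
  cause-specific hazard shapes cannot be emulated.
* The complete-case filter handles baseline missingness only; longitudinal
  missingness other than monotone dropout is not modelled.
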