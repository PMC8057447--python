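# cogjoint

Shared parameter joint models for longitudinal cognitive z-scores with
informative dropout.

## The problem

Longitudinal ageing cohorts measure cognition repeatedly — here as a global
cognitive z-score, the number of standard deviations a participant's battery
score sits from a reference population — and ask whether a time-dependent
exposure (surgery with general anesthesia after enrollment) changes the
annual rate of cognitive decline. Participants who develop dementia or die
stop contributing observations, and because low or fast-declining cognition
drives that dropout, the missing outcomes are *missing not at random* (MNAR):
a linear mixed model fitted to the observed data alone, which is valid under
missing at random (MAR), underestimates the exposure association.

`cogjoint` implements both analyses for cohorts with continuous, irregular
visit times:

* a **linear mixed effects model** (ML, not REML) with fixed effects for
  baseline covariates, time since enrollment `t`, covariate-by-time
  interactions, and the time-dependent exposure term
  `u = max(0, t - s)` (years since the first post-enrollment surgery, zero
  before exposure and for the never exposed), with random intercept, slope
  and post-exposure slope change:

  `y_ij = β₀ + βₓ'xᵢ + (βₜ + βₜₓ'xᵢ) t_ij + βₑ u_ij + b₀ᵢ + b₁ᵢ t_ij + b₂ᵢ u_ij + ε_ij`

* a **shared parameter model** coupling that submodel to a
  proportional-hazards model for time to dropout (dementia or death) through
  the same random effects:

  `hᵢ(t) = h₀(t) exp(γ'xᵢ + α₀b₀ᵢ + α₁b₁ᵢ + α₂b₂ᵢ)`,  `bᵢ ~ N(0, G)`

  with a piecewise-constant baseline hazard (closed-form cumulative hazard),
  fitted by a Metropolis-within-Gibbs sampler, and verified against an
  adaptive Gauss–Hermite quadrature of the marginal likelihood.

The coefficient of interest is `βₑ`, the change in the annual z-score slope
after exposure. The package also implements the surrounding analysis
apparatus: AIC selection of the random-effects structure, the composite
dropout endpoint rules (dementia diagnosis; death within 18 months of a
study visit; censoring at last known alive), reverse Kaplan–Meier follow-up,
post-dementia observation exclusion, complete-case baseline filtering, DIC
comparison of association structures, the dementia-only sensitivity
endpoint, and fixed-effects trajectory prediction.

Because the motivating cohort is not public, a first-class synthetic-data
module generates cohorts with the same statistical anatomy (≈1900 subjects
aged 70+, gamma-distributed inter-visit gaps with median 1.3 years,
exponential first-exposure clock, informative dropout through the shared
random effects) so the MAR-vs-MNAR comparison can be exercised end to end
under a known truth.

## Worked example

```python
from cogjoint import (ExperimentConfig, MCMCConfig, default_config, run_single)

cfg = ExperimentConfig(
    sim=default_config(n_subjects=600),      # MNAR truth: beta_e = -0.081
    mcmc=MCMCConfig(n_iter=4000, n_burnin=2000),
    master_seed=21,
)
report = run_single(cfg)
print(report.rounded()[["model", "diff_est", "diff_low", "diff_high"]])
print(f"relative difference: {report.relative_difference_pct:.0f}%")
```

which prints (seed 21, one simulated cohort):

```
                            model  diff_est  diff_low  diff_high
0                         lmm_mar    -0.062    -0.099     -0.026
1      lmm_mar_excl_post_dementia    -0.062    -0.099     -0.026
2           shared_parameter_mnar    -0.084    -0.120     -0.045
3  shared_parameter_dementia_only    -0.079    -0.120     -0.038
relative difference: 35%
```

The generating change in slope is −0.081. The MAR mixed model is attenuated
toward zero by the informative dropout (−0.062 here), the shared parameter
model moves the estimate back to the truth (−0.084, with the dementia-only
sensitivity fit in between), and the relative difference quantifies how much
larger in magnitude the MNAR-aware estimate is. Any single replicate is
noisy; `run_replicates` averages over cohorts — across 8 replicates at
n=600 the mean LMM estimate was −0.067 (bias +0.014) against −0.079
(bias +0.002) for the joint model.

There is also a CLI over the same pipeline:

```bash
cogjoint simulate --seed 1 --out scratch/cohort
cogjoint prepare  --data scratch/cohort --out scratch/prepared
cogjoint fit-lmm  --data scratch/prepared --out scratch/fits
cogjoint fit-joint --data scratch/prepared --out scratch/fits
cogjoint experiment --seed 1 --subjects 600 --out scratch/exp
cogjoint report --data scratch/cohort
```

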