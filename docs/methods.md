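# Methods

## The vibration-of-effects framework

The package studies a single exposure–outcome association estimated by a
Cox proportional-hazards model for all-cause mortality (or any
time-to-event outcome).  Let β̂ be the exposure's log hazard ratio under
one analytic choice.  Vibration of effects is the distribution of β̂ (and
its p-value) over a family of analyses:

* **Model vibration.**  The family is the power set of the k optional
  adjustment variables; baseline adjustments (age and sex in the bundled
  example) appear in every member, giving 2^k Cox fits on the full
  cohort.  Enumeration order is a binary counter over the optional
  variables (bit i = variable i included), so `model_id` is reproducible.
  k is capped at 20 unless the caller raises the cap, because 2^k fits
  must stay desk-scale.
* **Sampling vibration.**  The family is B simple random subsets, drawn
  without replacement, of size ⌊fraction·n⌋ (defaults B = 1000,
  fraction = 0.5), each refit with the favourite model — the
  all-adjustments specification unless overridden.  Subsets are drawn
  ignoring survey strata/clusters; design columns still enter each fit.
* **Measurement vibration.**  The family is B re-fits of the favourite
  model on cohorts with freshly injected measurement error.  Per
  iteration one parameter triple (ρ, sensitivity, specificity) is drawn —
  each uniform on its configured range — and applied to every corrupted
  variable; the noise itself is generated from an independent substream
  per variable, so errors across variables are uncorrelated.  Scenarios
  restrict the corruption to the exposure, to the (non-error-free)
  adjustments, or apply it to both.  Variables flagged `error_free`
  (age, sex, race/ethnicity in the example schema) and the outcome are
  never corrupted.

Summaries over each family, computed on converged fits only: the relative
hazard ratio RHR = q₉₉(HR)/q₁(HR), the relative p-value
RP = q₉₉(−log₁₀ p) − q₁(−log₁₀ p), counts of negative-significant /
non-significant / positive-significant fits at α = 0.05, and the Janus
flag (≥ 1 significant fit on each side of HR = 1).

## Measurement-error models

**Continuous (classical additive, non-differential).**  Observed
Z = X + U with U ⟂ X, U ~ N(0, Var(U)).  Given a target correlation ρ
between X and Z, Var(Z) = Var(X)/ρ², hence

    Var(U) = Var(X)/ρ² − Var(X).

The observed recordings are treated as the true X (their sample variance,
ddof = 1, estimates Var(X)), so the engine simulates *additional* error on
top of whatever the data already carry — a conservative reading.  A single
error-prone covariate's regression coefficient attenuates by the factor
ρ² (regression dilution), which the test suite verifies at ρ = 0.8.

**Binary (misclassification).**  Z | X=1 ~ Bernoulli(sensitivity),
Z | X=0 ~ Bernoulli(1 − specificity), independently per row.

**Ordinal (latent normal).**  Interior thresholds τ₁ < … < τ_{L−1} are
set from the empirical cumulative level frequencies through Φ⁻¹.  Each
row's latent value is drawn from the standard normal truncated to its
level's interval (inverse-CDF sampling), classical noise with variance
Var(U) = 1/ρ² − 1 is added, and the sum is rescaled by
1/√(1 + Var(U)) = ρ before re-discretisation with the same thresholds.
The rescaling is a deliberate design choice where the procedure was
genuinely open: it keeps the noisy latent exactly standard normal, so
level frequencies are preserved in distribution (not merely
approximately) and the latent correlation between clean and noisy values
is exactly ρ; with ρ = 1 the operation is the identity.  A latent value
landing exactly on a threshold is assigned to the upper level so the
noise-free path returns its input bit-for-bit.

**Default parameter ranges** (uniform draws per iteration): correlation
ρ ∈ [0.73, 0.9] for continuous and ordinal variables; sensitivity
∈ [0.56, 0.85] and specificity ∈ [0.73, 0.98] for binary variables.
These are literature-typical magnitudes for self-reported and
examination-based exposures in mortality cohorts.

## Estimation

Cox fits are delegated to lifelines (`CoxPHFitter`, Efron tie handling,
Newton optimisation).  When the schema declares design columns,
participant weights enter the partial likelihood, strata stratify the
baseline hazard, and the variance is the robust sandwich estimator
grouped by the cluster variable; without a design the model-based
variance is used (on well-specified independent data the two Wald
p-values agree closely, which is tested).  P-values use the normal
approximation to the Wald statistic and are floored at the smallest
positive double to keep −log₁₀ p finite.

A degenerate fit (constant exposure, zero events in a subsample,
non-convergence, non-finite coefficients) is returned as a
`converged=False` estimate rather than raised: per-iteration failures are
retained in the output CSV for transparency but excluded from percentile
summaries, and an engine aborts only when more than 5 % of its fits fail.

Standardisation: a continuous exposure is standardised (mean 0, sample
SD 1) once when a cohort is loaded or generated, so hazard ratios are per
SD.  Under measurement vibration the corrupted exposure is re-standardised
after error injection, keeping the per-SD scale comparable across draws;
when a draw injects no error the column is left untouched so the no-error
limit reproduces the reference fit exactly.

## Quantile and boundary conventions

Percentile levels default to 1 and 99; quantiles interpolate linearly
between order statistics (Hyndman–Fan type 7, numpy's default).  Note
that RHR(hrs) = RHR(1/hrs) holds exactly only when the percentiles land
on order statistics, since linear interpolation does not commute with
reciprocals; the convention is fixed and documented rather than adjusted.
A log hazard ratio of exactly 0 counts as non-significant regardless of
its p-value.  Missing data are handled by one complete-case pass over all
schema variables at load time, so every engine sees identical rows.

## Synthetic cohorts

The generator draws latent rows from a multivariate normal with a given
correlation matrix (Gaussian copula); continuous covariates are the
latents, binary/ordinal covariates are thresholded latents.  Event times
are exponential with rate λ₀·exp(Σⱼ βⱼxⱼ) — a Cox model with constant
baseline hazard — and censoring is exponential with rate c (administrative
censoring at +∞ when c = 0).  Exponential survival gives closed-form
oracles: the two-group hazard ratio equals the rate ratio, and the event
fraction is monotone in c.

`spec_from_cohort` adopts a real cohort's dependence and effects:
pairwise latent correlations via Pearson (continuous–continuous),
moment-based polyserial (continuous–discrete: Cov(Z_x, score) =
ρ·Σⱼφ(τⱼ)) and polychoric estimates (discrete–discrete: a bracketed 1-D
root solve equating the observed score covariance to its bivariate-normal
expression), with eigenvalue clipping to the nearest positive-definite
matrix when needed; β from the all-adjustments Cox fit; λ₀ from the
exponential-likelihood estimate D/Σ tᵢ·exp(xᵢβ̂) and c from the censored
count per unit follow-up.  Rank-based shortcuts (e.g. the Spearman sine
transformation) were rejected because they are biased toward zero for
thresholded margins and would not recover the latent structure to the
accuracy the round-trip tests require.

The bundled example specification (`example_spec`) has 16 covariates —
one continuous exposure, error-free continuous age and binary sex as
baseline adjustments, and 13 optional adjustments of mixed type including
an error-free 4-level race/ethnicity variable — with AR(1) latent
correlations (parameter 0.3), modest per-SD log hazard ratios
(|β| ≤ 0.4, age the strongest), λ₀ = 0.08 and censoring rate 0.15,
yielding roughly a one-third event fraction.  These choices emulate the
dependence strength, covariate mix and event rates of a mid-size
examination-survey mortality cohort.  What the generator does **not**
emulate: real survey weighting and multi-stage cluster sampling,
non-proportional hazards, nonlinear covariate effects, informative
censoring, and item-level missingness.  Tests passing on these cohorts
therefore validate the machinery and its statistical calibration, not the
substantive behaviour of any particular real cohort.

## Reproducibility and problem sizes

Every stochastic engine takes a master seed feeding a
`numpy.random.SeedSequence`; one independent substream is spawned per
iteration, so runs are reproducible and iteration results are independent
of execution order.  The test suite exercises the engines at reduced
problem sizes chosen to keep the full run desk-scale while leaving the
Monte-Carlo checks well-powered: full model-universe fitting at k = 8 on
n = 2000 (256 fits) alongside count-only enumeration at k = 13; the
default B = 1000 sampling protocol on an n = 1000 cohort; B = 50
replicate-level comparisons for the sample-size ordering property
(20 replicates at n ∈ {500, 5000}); and generator calibration at
n = 100 000–200 000 where tolerances are tightest.

## Known limitations

Only classical additive, non-differential error with uncorrelated errors
across variables is modelled; systematic, multiplicative,
heteroscedastic or differential error and outcome misclassification are
out of scope, as are error-correction methods (SIMEX, regression
calibration) — the framework quantifies sensitivity, it does not correct
estimates.  The model universe covers inclusion/exclusion of linear main
effects only (no interactions or splines), and survey designs enter as
weights plus cluster-robust variance rather than full linearisation.
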