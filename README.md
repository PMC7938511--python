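# voe — vibration of effects for Cox exposure–mortality analyses

When epidemiologists estimate the association between one exposure and
time-to-event mortality, the reported hazard ratio is only one point in a
space of defensible analyses: which adjustment variables to include, which
subsample of the cohort happened to be observed, and how precisely the
covariates were measured.  `voe` quantifies this *vibration of effects* —
the variability of the estimate for a single association — along three
axes:

* **Model vibration** — refit the Cox model for every subset of the k
  optional adjustment variables (2^k specifications), with baseline
  adjustments such as age and sex forced into every model.
* **Sampling vibration** — refit a chosen *favourite model* (by default
  the one with all adjustments) on B random subsets without replacement of
  size ⌊fraction·n⌋.
* **Measurement vibration** — B times, draw measurement-error parameters
  from uniform ranges, corrupt the non-error-free variables, and refit.
  Continuous variables get classical additive error Z = X + U with
  U ~ N(0, Var(X)/ρ² − Var(X)) targeting a correlation ρ between true and
  observed values (default ρ ∈ [0.73, 0.9]); binary variables are
  misclassified via sensitivity ∈ [0.56, 0.85] and specificity
  ∈ [0.73, 0.98]; ordinal variables are perturbed through a latent-normal
  representation.  Error can hit the exposure only, the adjustments only,
  or both.

Each run is summarised by the **relative hazard ratio**
RHR = q₉₉(HR)/q₁(HR), the **relative P-value**
RP = q₉₉(−log₁₀ p) − q₁(−log₁₀ p), significance counts at α = 0.05, and
the **Janus pattern** flag (significant estimates in both the harmful and
protective direction).  Volcano plots (HR vs −log₁₀ p) visualise each run,
with the unperturbed favourite-model fit marked by a cross.

Fits use lifelines' Cox proportional-hazards implementation (Efron ties),
with survey weights, baseline-hazard strata and a cluster-robust sandwich
variance when the cohort schema declares design columns.

## Worked example

```python
from voe import generate_cohort, example_spec, MeasurementVibration

# 2000-person synthetic mortality cohort: 1 continuous exposure,
# age/sex baseline, 13 mixed-type optional adjustments
cohort = generate_cohort(example_spec(2000), seed=42)
result = MeasurementVibration(cohort, scenario="both", B=200).fit(seed=42)
print(result.summary())
```

```
Vibration of effects — measurement vibration (scenario: both)
============================================================
fits                                 200
non-converged fits                     0
RHR (P99/P1)                      1.1402
RP (spread of -log10 p)           6.9509
Janus pattern                      False
negative significant                   0
non-significant                        0
positive significant                 200
reference HR (p)              1.2693 (3.78e-09)
```

The reference fit (no injected error) gives HR 1.27 per SD of the
exposure.  Injecting realistic measurement error into the exposure and the
error-prone adjustments moves the estimate over a 1.14-fold range between
the 1st and 99th percentile, and the p-value spreads over almost 7 orders
of magnitude — but every draw stays positive-significant, so the
qualitative conclusion is robust here.  `result.plot_volcano("out.png")`
draws the corresponding volcano plot, and `result.save(out_dir)` writes a
long-format `estimates.csv` plus a `summary.json`.

The same cohort feeds `ModelVibration` (all 2^13 = 8192 adjustment sets)
and `SamplingVibration` (default B = 1000 half-cohort subsets), and
`vibration_over_sample_sizes` sweeps all three engines across cohort sizes
to show how sampling vibration shrinks toward RHR = 1 with n while model
and measurement vibration persist.

A command-line interface mirrors the library:

```bash
voe simulate --n 2000 --seed 42 --out-dir sim/
voe measurement --cohort sim/cohort.csv --schema sim/schema.yaml \
    --scenario both --B 1000 --seed 42 --out-dir run/
voe sweep --sizes 500,1000,5000 --B 200 --seed 1 --out-dir sweep/
```

Real cohorts enter as a CSV plus a YAML/JSON schema assigning each column
a kind (continuous/binary/ordinal), a role (exposure, adjustment,
baseline_adjustment, time, event, weight, stratum, cluster) and an
error-free flag; rows with missing values are dropped once at load and a
continuous exposure is standardised so hazard ratios are per SD.

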