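# Methods

## The model

Prognosis after a diagnosis of nonmetastatic prostate cancer involves two
competing causes of death: the cancer itself (PCSM, prostate-cancer-specific
mortality) and everything else (NPCM).  The package implements an
individualised prognostic model of the PREDICT Prostate family: two
cause-specific Cox proportional-hazards models whose predictions are combined
into competing-risk-adjusted cumulative mortality.

Each cause has a centered prognostic index — a linear predictor over the
diagnostic covariates:

```
piPCSM = b_age * [(age/10)^3 - 341.16]
       + b_psa * [ln((PSA+1)/100) + 1.6364]
       + b_gg(grade group) + b_t(T-stage) + b_tx(treatment)
       + ln(PPC multiplier)                      (optional biopsy extension)

piNPCM = b_agel * (age - 69.87) + b_com * comorbidity
```

Continuous covariates enter through fractional-polynomial (FP) transforms; the
bracketed constants centre each transform at its development-sample mean, so
the reference patient (grade group 1, T1, conservative management, covariates
at centring values, biopsy cores unknown) has prognostic index 0.  The shipped
coefficients are the published point estimates — grade-group hazard ratios
1.32/1.73/2.10/3.93, T-stage 1.18/1.49/1.88, radical treatment 0.50, primary
hormone monotherapy 2.48, PSA-transform 1.204, age-transform 1.003; NPCM age
1.13 per year and comorbidity 1.89 — stored as log hazard ratios at full
precision in `src/predictprostate/data/default_model.json`.

The marginal (independent-risk) cumulative risk of each cause is

```
H_cause(t) = 1 - exp(-exp(pi_cause) * Lambda0_cause(t))
```

where `Lambda0` is the smoothed cumulative baseline hazard, and the combined
quantities reported to a patient are

```
R_OM  = 1 - (1 - H_PCa)(1 - H_NPC)
R_PCa = R_OM * H_PCa / (H_PCa + H_NPC)
R_NPC = R_OM * H_NPC / (H_PCa + H_NPC)
```

The partition `R_PCa + R_NPC = R_OM` holds identically; the (0, 0) corner of
the combination returns zeros (R_OM is 0 there, so the split convention is
inconsequential).  Important caveat, quantified below: the proportional split
is an *approximation* to the cumulative incidence of a latent-failure-time
mechanism; the overall-mortality curve is exact.

Treatment benefit is the difference in R_OM between the conservative and
radical scenarios at the 10- or 15-year horizon.  Uncertainty around the
treatment effect is displayed as an efficacy band: overall-survival curves at
efficacy fractions f ∈ {0, 0.25, 0.5, 0.75, 1} of the radical log-hazard
ratio — the proportional-hazards-consistent interpolation between no effect
(f = 0, the conservative curve) and the full data-derived effect.  Because
risks compete, the overall-survival gain is always at most the reduction in
R_PCa; the gap widens with age and comorbidity.  Hormone monotherapy is
supported as a scenario but flagged: its hazard ratio reflects registry
selection of frailer men, not a randomised effect.

### The biopsy-core extension

Percentage of positive cores (PPC = cores positive / cores taken) enters as a
dichotomous PCSM multiplier: 0.54 below 50% involvement, 1.78 at or above,
and exactly 1.0 when core counts are unknown, so the base model is recovered.
The "weight adjustment" of these multipliers is implemented as centring: the
sub-cohort-average multiplier is constrained to 1, which with the shipped
pair implies a ≥50% prevalence of (1−0.54)/(1.78−0.54) ≈ 37.1% — the value
the default PPC sub-cohort scenario uses.

### Population-averaged comorbidity

When comorbidity is unavailable for an entire cohort, the NPCM hazard is
multiplied by the population average `(1 − p) + p·HR` at prevalence
p = 10.21%, spreading the binary effect evenly.

## Model development pipeline

`build_model` reproduces the development procedure on any compliant cohort:

1. administrative censoring at 15 years; seeded 70:30 split
   (floor(n·ratio) development records);
2. cause-specific Cox fits treating the competing cause as censoring —
   partial likelihood with Efron's tie correction (plain Breslow when event
   times are distinct, where the two coincide);
3. backwards elimination at α = 0.05: each round drops the variable with the
   largest multi-degree-of-freedom Wald p-value (factors tested jointly),
   with FP forms re-selected after every structural change.  Wald rather
   than likelihood-ratio p-values — the conventional choice where the source
   procedure is unstated;
4. FP form selection by the closed test over the standard 8-power set
   {−2, −1, −0.5, 0, 0.5, 1, 2, 3}: best FP2 against the null (4 df),
   against the straight line (3 df), against best FP1 (2 df), stopping at
   the simplest adequate form.  Repeated powers use the x^p, x^p·ln x
   convention; selected transforms are centred at development-sample means,
   while refits of the published structure keep the printed constants;
5. Breslow estimation of the cumulative baseline hazard at the centred
   configuration, then FP smoothing of its logarithm against time by least
   squares (FP1 unless FP2 improves at the 5% F-test).  Monotonicity of the
   smoothed cumulative hazard is checked on a 0.1-year grid and flagged,
   never enforced;
6. the PPC extension: candidate codings of core involvement (continuous,
   dichotomised at 50%, tertiles) fitted with the base prognostic index as a
   fixed offset — base coefficients untouched by construction — and compared
   by likelihood ratio, AIC and BIC, ties resolved toward the simplest
   coding.

A proportional-hazards diagnostic (correlation of Schoenfeld residuals with
event time, per design column) is reported per fit.  All stochastic steps
take explicit seeds (default 20251201); rebuilding with the same seed yields
a bit-identical coefficient file.

## Synthetic cohorts

The generator emulates a diagnosis registry of ~10,000 men accrued over 11
years with a fixed administrative censor date:

* age: truncated normal, mean 69.9, SD 8.3, range [40, 95] years;
* PSA: log-normal whose truncation below 100 ng/mL has mean 18.4 and SD
  17.5 (the printed moments are post-exclusion, so the underlying parameters
  are solved from the truncated-moment equations);
* grade group (33.0/29.9/14.7/10.2/12.2%), T-stage (53.7/31.8/13.7/0.8%),
  treatment (conservative 19.8%, radical 48.7%, hormone 31.5%),
  comorbidity Bernoulli(10.21%) — all sampled independently by default;
  an optional knob ties treatment probabilities to grade group to mimic
  confounding by indication;
* event times: latent cause-specific times by inverse-transform sampling —
  solve `Lambda0(t)·exp(pi) = −ln U` by bracketed bisection (64 halvings of
  (0, 15], well below the 1e−8-year tolerance); the observed time is the
  minimum of the two latent times, the censoring time and 15 years, the
  event the cause of that minimum;
* censoring: entry uniform over the 11-year accrual window with
  administrative cutoff 16.75 years after the window opens, plus an
  independent exponential loss rate of 0.02/year.

The shipped baselines are Weibull-form FP functions of time,
`log Lambda0(t) = a + b·ln t`, with (a, b) = (−6.2667, 1.5807) for PCSM and
(−4.8210, 1.4614) for NPCM.  The published smoothing coefficients live only
in a supplementary appendix, so these were calibrated once, jointly with the
loss rate, so that the default cohort reproduces the registry's printed
cohort-level figures; the calibrated defaults achieve crude
cancer-specific mortality ≈ 1.46 and overall ≈ 4.6 per 100 person-years,
≈ 37% censored before 10 years, and 10-year cause-specific death fractions
within half a percentage point of the printed 10.2%/22.3%.  The calibration
targets are printed registry statistics fixed in advance, not quantities
tuned against this package's own tests.

What the generator does *not* emulate: covariate correlations (PSA–grade,
age–treatment — the registry publishes only marginals), regional case-mix
differences, or cause-of-death misclassification.  Passing recovery tests on
these cohorts therefore demonstrates the pipeline's correctness under the
model's own assumptions, not robustness to real-registry violations of them.

## Validation statistics

**Calibration / goodness of fit.**  Observed deaths are compared with
model-expected deaths in quintiles of predicted risk (or user strata) via
`chi2 = Σ (O−E)²/E`.  Expected counts default to the cumulative-hazard
basis: each subject contributes `exp(pi)·Lambda0(min(follow-up, horizon))`,
the expectation accumulated over their own at-risk time.  This construction
is exactly centred under a correct model with Poisson-like group variance;
simulation at n = 2,000 (600 replicates) puts the type-I error at
4.5–4.8% for all three causes with the chi-square referred to G degrees of
freedom, against 7–9% with G−1 — external validation imposes no fitted-total
constraint, so G is the default in `calibration_quintiles` (both choices
remain available, and the bare `gof_test` utility keeps G−1).  A risk-scale
basis (each subject contributes the competing-risk-adjusted cumulative risk)
is provided for report readability but is only approximately centred.
Percent difference is (O−E)/n·100: observed excess is positive.

**Discrimination.**  Harrell's concordance index on the predicted 10- or
15-year cause-specific cumulative risk, with competing-cause deaths censored
at their death time.  Pairs are enumerated exactly (vectorised, blocked);
confidence intervals and paired model comparisons use the
leave-one-subject-out jackknife, which a brute-force pair-enumeration oracle
and an independent library implementation cross-check in the tests.

**Comparators.**  CAPRA points (age, PSA bands, Gleason-pattern points
mapped from grade group, stage, ≥34% cores), three-tier EAU groups, and a
versioned post-2018 NCCN ruleset including the ≥50% positive-core criterion.
With collapsed staging, T2 is read as T2a and T3 as T3a; NCCN's very-low
tier is folded into low because PSA density is not recorded.  Missing core
counts contribute no CAPRA points (no imputation).

## Numerical choices and edge cases

* FP evaluation demands a strictly positive argument for logarithmic or
  negative powers and raises a domain error naming the variable.
* Baseline inversion returns +inf (no event within the 15-year domain) for
  draws beyond `Lambda0(15)`.
* PSA exactly 100 ng/mL is excluded (boundary honoured as printed);
  cohort records missing any key predictor are excluded with
  machine-readable reasons, and the filter is idempotent.
* T-stage subcategories (e.g. T2c) are not accepted; upstream mapping to
  1–4 is required.
* Degenerate calibration input (all predictions equal) falls back to a
  single group with a warning and no chi-square.
* Factor levels with zero events are flagged with a warning and left in the
  fit rather than silently dropped.

## Known limitations

* **The proportional cause split is an approximation.**  For any
  latent-failure-time mechanism consistent with the marginal risks H, the
  exact cause-specific cumulative incidence integrates survival from both
  causes against each cause's hazard.  Against 100,000 uncensored simulated
  subjects, predicted and empirical overall mortality agree within
  Monte-Carlo noise at 5/10/15 years, but the split over-attributes about
  0.9 (10y) and 2.0 (15y) percentage points to cancer death at cohort
  level.  The formulas are retained as the model's defining output; the
  dedicated oracle test documents the deviation.
* Covariate independence in the generator (above).
* The hormone-monotherapy hazard ratio is a selection-biased registry
  estimate and is flagged as such in prediction output.
* Simulation-based test sizes (e.g. 20-seed recovery at n = 7,063, 500
  GOF replicates at n = 2,000, 1,500-subject discrimination cohorts) were
  chosen to keep the default suite fast while leaving clear Monte-Carlo
  margins; all are parameters, not constants.
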