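# predictprostate

Individualised prognosis at diagnosis for nonmetastatic prostate cancer,
implemented as two cause-specific survival models combined under competing
risks — the PREDICT Prostate modelling approach — together with the full
model-development pipeline, validation statistics, comparator
risk-stratification scores, and a synthetic registry-like cohort generator.

**Who it is for.** Biostatisticians and clinical-prediction-model researchers
who need a transparent, testable implementation of an individualised
prostate-cancer prognostic model: to compute patient-level risk and
treatment-benefit estimates from routine diagnostic data, to rebuild the
model on their own registry extracts, or to study the method's operating
characteristics on simulated cohorts.

## The model

For a man diagnosed with nonmetastatic disease, two proportional-hazards
models give centered prognostic indices from age, PSA, histological grade
group (1–5), clinical T-stage (1–4), primary treatment and, optionally,
biopsy core involvement (cancer-specific mortality, PCSM) and from age and
comorbidity (other-cause mortality, NPCM).  Continuous covariates enter
through fractional-polynomial transforms, e.g. `(age/10)^3 − 341.16` and
`ln((PSA+1)/100) + 1.6364` for PCSM.  Marginal cumulative risks

    H_cause(t) = 1 − exp(−exp(pi_cause) · Λ0_cause(t))

are combined into competing-risk-adjusted mortality

    R_OM = 1 − (1 − H_PCa)(1 − H_NPC),
    R_PCa = R_OM · H_PCa/(H_PCa + H_NPC),   R_NPC = R_OM − R_PCa,

and treatment benefit is the overall-survival difference between the
conservative-management and radical-treatment scenarios, shown with a
0–100% efficacy band.  The shipped coefficients are the published hazard
ratios (e.g. grade group 5: 3.93; radical treatment: 0.50; comorbidity on
NPCM: 1.89); see `docs/methods.md` for the full account, including how the
default baseline hazards were calibrated to printed registry-level rates.

## Worked example

```
$ predict-prostate predict --age 65 --psa 10 --grade-group 2 --t-stage 2 \
      --treatment conservative --horizon 15
15-year risks under conservative:
  PCa death 13.3%   other death 20.4%   any death 33.7%
  radical vs conservative: PCa mortality 13.3% -> 7.1%, overall survival gain 5.4%
```

Reading: a 65-year-old with PSA 10 ng/mL, grade group 2, T2 disease managed
conservatively has an estimated 13.3% chance of dying of prostate cancer
within 15 years and a 33.7% chance of dying of any cause.  Radical treatment
would roughly halve the cancer-specific risk (to 7.1%), but because other
causes of death compete, the estimated overall-survival gain is 5.4
percentage points, not the full 6.2-point cancer-mortality reduction.
`--json` emits the structured report, `--curves out.csv` the full risk
curves, `--cores 6/12` adds the biopsy-core multiplier.

The same computation in Python:

```python
from predictprostate import PatientRecord, load_default_model, treatment_benefit

model = load_default_model()
patient = PatientRecord(id="example", age=65, psa=10.0, grade_group=2,
                        t_stage=2, treatment="conservative")
benefit = treatment_benefit(patient, model, horizon=15)
print(round(benefit.pcsm_conservative, 3),   # 0.133
      round(benefit.pcsm_radical, 3),        # 0.071
      round(benefit.os_gain, 3))             # 0.054
```

Other entry points: `predict-prostate fit` runs the development pipeline
(split, MFP selection, backwards elimination, baseline smoothing) on a
cohort CSV; `predict-prostate validate` produces quintile calibration and
concordance reports; `predict-prostate simulate` writes a synthetic
registry-like cohort with a provenance sidecar.  The same surfaces are
available programmatically (`PredictModelBuilder`, `calibration_quintiles`,
`harrell_c`, `CohortScenario`, ...).

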