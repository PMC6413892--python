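"""Construction of the shipped model from the published hazard ratios.

The cause-specific coefficients are the published point estimates entered as
log hazard ratios, with the published centering constants for the continuous
transforms:

    PCSM:  age through (age/10)^3 - 341.16, PSA through
           ln((PSA+1)/100) + 1.6364, grade group (ref 1), T-stage (ref 1),
           primary treatment (ref conservative management)
    NPCM:  age - 69.87 (linear), binary comorbidity (ref 0)

The published baseline-hazard smoothing coefficients are not reproduced in
the primary text, so the shipped baselines are Weibull-form FP functions of
time (log Lambda0 linear in ln t) calibrated once so that the default
synthetic cohort reproduces the development registry's printed cohort-level
rates (crude prostate-cancer-specific mortality 1.46 and overall mortality
4.64 per 100 person-years, ~10.2%/22.3% 10-year cause-specific death
fractions, ~37% censored before 10 years).  See docs/methods.md.
"""

from __future__ import annotations

import math

from .model import (
    CategoricalTerm,
    CauseSpecificModel,
    FPBaseline,
    FPTerm,
    PredictModel,
)

__all__ = ["build_published_model", "PUBLISHED_HRS"]

# point estimates as printed; betas below are their natural logarithms
PUBLISHED_HRS = {
    "pcsm": {
        "age_fp": 1.003,
        "psa_fp": 1.204,
        "grade_group": {"1": 1.0, "2": 1.32, "3": 1.73, "4": 2.10, "5": 3.93},
        "t_stage": {"1": 1.0, "2": 1.18, "3": 1.49, "4": 1.88},
        "treatment": {"conservative": 1.0, "radical": 0.50, "hormone": 2.48},
    },
    "npcm": {"age": 1.13, "comorbidity": {"0": 1.0, "1": 1.89}},
    "ppc": {"lt50": 0.54, "ge50": 1.78, "unknown": 1.0},
}

# calibrated default baselines: log Lambda0(t) = intercept + coef * ln t
# (values fixed by the one-off cohort-level calibration described above)
DEFAULT_PCSM_BASELINE = {"intercept": -6.2667, "slope": 1.5807}
DEFAULT_NPCM_BASELINE = {"intercept": -4.8210, "slope": 1.4614}

COMORBIDITY_PREVALENCE = 0.1021


def _log_map(hrs: dict) -> dict[str, float]:
    return {k: math.log(v) for k, v in hrs.items()}


def build_published_model(
    pcsm_baseline: FPBaseline | None = None,
    npcm_baseline: FPBaseline | None = None,
    include_ppc: bool = True,
) -> PredictModel:
    """Assemble the shipped two-cause model from the published coefficients."""
    if pcsm_baseline is None:
        pcsm_baseline = FPBaseline(
            powers=(0.0,),
            coefs=(DEFAULT_PCSM_BASELINE["slope"],),
            intercept=DEFAULT_PCSM_BASELINE["intercept"],
        )
    if npcm_baseline is None:
        npcm_baseline = FPBaseline(
            powers=(0.0,),
            coefs=(DEFAULT_NPCM_BASELINE["slope"],),
            intercept=DEFAULT_NPCM_BASELINE["intercept"],
        )
    p = PUBLISHED_HRS["pcsm"]
    pcsm = CauseSpecificModel(
        cause="pcsm",
        fp_terms=(
            FPTerm(
                variable="age",
                powers=(3.0,),
                betas=(math.log(p["age_fp"]),),
                pre_scale=10.0,
                centers=(341.16,),
            ),
            FPTerm(
                variable="psa",
                powers=(0.0,),
                betas=(math.log(p["psa_fp"]),),
                pre_shift=1.0,
                pre_scale=100.0,
                centers=(-1.6364,),
            ),
        ),
        categorical_terms=(
            CategoricalTerm("grade_group", "1", _log_map(p["grade_group"])),
            CategoricalTerm("t_stage", "1", _log_map(p["t_stage"])),
            CategoricalTerm("treatment", "conservative", _log_map(p["treatment"])),
        ),
        baseline=pcsm_baseline,
    )
    q = PUBLISHED_HRS["npcm"]
    npcm = CauseSpecificModel(
        cause="npcm",
        fp_terms=(
            FPTerm(
                variable="age",
                powers=(1.0,),
                betas=(math.log(q["age"]),),
                centers=(69.87,),
            ),
        ),
        categorical_terms=(
            CategoricalTerm("comorbidity", "0", _log_map(q["comorbidity"])),
        ),
        baseline=npcm_baseline,
    )
    return PredictModel(
        pcsm=pcsm,
        npcm=npcm,
        ppc_hr=dict(PUBLISHED_HRS["ppc"]) if include_ppc else None,
        metadata={
            "version": "published-coefficients",
            "comorbidity_prevalence": COMORBIDITY_PREVALENCE,
            "power_set": [-2, -1, -0.5, 0, 0.5, 1, 2, 3],
        },
    )
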