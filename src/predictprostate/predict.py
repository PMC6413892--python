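"""Individual risk prediction under competing mortality causes.

Each cause-specific model yields a centered prognostic index pi and a marginal
(independent-risk) cumulative risk H(t) = 1 - exp(-exp(pi) * Lambda0(t)).
Because prostate-cancer death and other-cause death compete, the cumulative
risks reported to a patient are the combined quantities

    R_OM  = 1 - (1 - H_PCa) (1 - H_NPC)
    R_PCa = R_OM * H_PCa / (H_PCa + H_NPC)
    R_NPC = R_OM * H_NPC / (H_PCa + H_NPC)

which satisfy R_PCa + R_NPC = R_OM identically.  Treatment benefit is the
difference in R_OM between the conservative-management and radical-treatment
scenarios, presented with an efficacy band spanning 0-100% of the full
treatment effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    CauseSpecificModel,
    FPBaseline,
    PatientRecord,
    PredictModel,
)

__all__ = [
    "prognostic_index",
    "cohort_linear_predictor",
    "marginal_cause_risk",
    "combine_competing_risks",
    "predict_curves",
    "treatment_benefit",
    "ppc_multiplier",
    "population_comorbidity_adjustment",
    "RiskPrediction",
    "TreatmentBenefit",
    "DEFAULT_PPC_HR",
]

DEFAULT_PPC_HR: Mapping[str, float] = {"lt50": 0.54, "ge50": 1.78, "unknown": 1.0}

# default time grid: quarter-year resolution, includes the 10- and 15-year
# canonical horizons
DEFAULT_GRID = np.round(np.arange(0.25, 15.0 + 1e-9, 0.25), 10)


def ppc_multiplier(
    record: PatientRecord, hr_map: Mapping[str, float] | None = None
) -> float:
    """PCSM hazard multiplier from percentage of positive biopsy cores.

    Dichotomised at 50% core involvement; a multiplier of exactly 1.0 applies
    when core counts are unavailable, so the base model is unchanged.
    """
    hr_map = DEFAULT_PPC_HR if hr_map is None else hr_map
    frac = record.ppc_fraction()
    if frac is None:
        return float(hr_map["unknown"])
    return float(hr_map["ge50"] if frac >= 0.5 else hr_map["lt50"])


def population_comorbidity_adjustment(prevalence: float, hr: float) -> float:
    """Population-averaged NPCM hazard multiplier for unknown comorbidity.

    When comorbidity status is unavailable cohort-wide, the binary effect is
    spread evenly at the development-cohort prevalence:
    (1 - p) * 1 + p * hr.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    return (1.0 - prevalence) + prevalence * hr


def _ppc_log_multipliers(
    cores_positive, cores_total, hr_map: Mapping[str, float]
) -> np.ndarray:
    cp = np.asarray(pd.to_numeric(pd.Series(cores_positive), errors="coerce"))
    ct = np.asarray(pd.to_numeric(pd.Series(cores_total), errors="coerce"))
    known = np.isfinite(cp) & np.isfinite(ct) & (ct > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ge50 = known & (cp / ct >= 0.5)
    out = np.full(cp.shape, np.log(hr_map["unknown"]))
    out[known & ~ge50] = np.log(hr_map["lt50"])
    out[ge50] = np.log(hr_map["ge50"])
    return out


def cohort_linear_predictor(
    df: pd.DataFrame,
    model: PredictModel,
    cause: str,
    treatment_override: str | None = None,
    include_ppc: bool = True,
) -> np.ndarray:
    """Vectorised centered prognostic index for every row of a cohort frame.

    Cohort-wide unknown comorbidity rows receive the population-averaged
    multiplier on the NPCM side; unknown biopsy core counts contribute
    multiplier 1 on the PCSM side.
    """
    cm = model.cause_model(cause)
    n = len(df)
    pi = np.zeros(n)
    for term in cm.fp_terms:
        pi = pi + term.contribution(df[term.variable].to_numpy(dtype=float))
    for cat in cm.categorical_terms:
        if cat.variable == "treatment" and treatment_override is not None:
            pi = pi + cat.beta_for(treatment_override)
            continue
        col = df[cat.variable]
        if cat.variable == "comorbidity":
            vals = pd.to_numeric(col, errors="coerce")
            unknown = vals.isna().to_numpy()
            prev = float(model.metadata.get("comorbidity_prevalence", 0.1021))
            hr1 = float(np.exp(cat.beta_for(1)))
            adj = np.log(population_comorbidity_adjustment(prev, hr1))
            contrib = np.where(
                unknown,
                adj,
                [0.0 if u else cat.beta_for(int(v)) for v, u in zip(vals.fillna(0), unknown)],
            )
            pi = pi + contrib
        else:
            pi = pi + np.asarray([cat.beta_for(v) for v in col])
    if (
        cause.lower() == "pcsm"
        and include_ppc
        and model.ppc_hr is not None
        and "cores_positive" in df.columns
        and "cores_total" in df.columns
    ):
        pi = pi + _ppc_log_multipliers(
            df["cores_positive"], df["cores_total"], model.ppc_hr
        )
    return pi


def prognostic_index(
    record: PatientRecord,
    model: PredictModel,
    cause: str,
    treatment_override: str | None = None,
) -> float:
    """Centered log-hazard prognostic index for one patient and one cause.

    Zero for the reference patient: all factors at reference level,
    continuous covariates at their centering values, biopsy cores unknown.
    """
    cm = model.cause_model(cause)
    pi = 0.0
    values = {"age": record.age, "psa": record.psa}
    for term in cm.fp_terms:
        pi += float(term.contribution(values[term.variable]))
    for cat in cm.categorical_terms:
        if cat.variable == "treatment":
            level = treatment_override or record.treatment
            pi += cat.beta_for(level)
        elif cat.variable == "comorbidity":
            if record.comorbidity is None:
                prev = float(model.metadata.get("comorbidity_prevalence", 0.1021))
                hr1 = float(np.exp(cat.beta_for(1)))
                pi += float(np.log(population_comorbidity_adjustment(prev, hr1)))
            else:
                pi += cat.beta_for(int(record.comorbidity))
        elif cat.variable == "grade_group":
            pi += cat.beta_for(record.grade_group)
        elif cat.variable == "t_stage":
            pi += cat.beta_for(record.t_stage)
        else:  # pragma: no cover - models fitted on extra factors
            raise ValueError(f"no record field for variable {cat.variable!r}")
    if cause.lower() == "pcsm" and model.ppc_hr is not None:
        pi += float(np.log(ppc_multiplier(record, model.ppc_hr)))
    return pi


def marginal_risk_from_cumhaz(pi, cumhaz) -> np.ndarray:
    """Marginal cumulative risk 1 - exp(-exp(pi) * Lambda0(t))."""
    return 1.0 - np.exp(-np.exp(np.asarray(pi, float)) * np.asarray(cumhaz, float))


def marginal_cause_risk(pi: float, baseline: FPBaseline, t) -> np.ndarray:
    """Cumulative risk of one cause ignoring the competing cause."""
    return marginal_risk_from_cumhaz(pi, baseline.cumhaz(t))


def combine_competing_risks(h_pca, h_npc):
    """Combine two marginal cumulative risks into competing-risk quantities.

    Returns (R_OM, R_PCa, R_NPC).  The partition R_PCa + R_NPC = R_OM holds
    identically; the (0, 0) corner returns zeros (R_OM is 0 there, so any
    split convention is inconsequential).
    """
    h_pca = np.asarray(h_pca, dtype=float)
    h_npc = np.asarray(h_npc, dtype=float)
    if np.any((h_pca < 0) | (h_pca > 1) | (h_npc < 0) | (h_npc > 1)):
        raise ValueError("marginal risks must lie in [0, 1]")
    r_om = 1.0 - (1.0 - h_pca) * (1.0 - h_npc)
    total = h_pca + h_npc
    with np.errstate(invalid="ignore", divide="ignore"):
        r_pca = np.where(total > 0, r_om * h_pca / np.where(total > 0, total, 1.0), 0.0)
        r_npc = np.where(total > 0, r_om * h_npc / np.where(total > 0, total, 1.0), 0.0)
    return r_om, r_pca, r_npc


def cohort_risk_at(df: pd.DataFrame, model: PredictModel, t):
    """Vectorised competing-risk cumulative risks for a cohort at time(s) t.

    ``t`` may be a scalar horizon or one evaluation time per row.  Returns
    (R_OM, R_PCa, R_NPC) arrays.
    """
    pi_p = cohort_linear_predictor(df, model, "pcsm")
    pi_n = cohort_linear_predictor(df, model, "npcm")
    t = np.asarray(t, dtype=float)
    h_p = marginal_risk_from_cumhaz(pi_p, model.pcsm.baseline.cumhaz(t))
    h_n = marginal_risk_from_cumhaz(pi_n, model.npcm.baseline.cumhaz(t))
    return combine_competing_risks(h_p, h_n)


@dataclass
class RiskPrediction:
    """Time-indexed risk curves for one patient under one treatment scenario."""

    times: np.ndarray
    h_pca: np.ndarray
    h_npc: np.ndarray
    r_om: np.ndarray
    r_pca: np.ndarray
    r_npc: np.ndarray
    pi_pcsm: float
    pi_npcm: float
    scenario: str

    def at(self, t: float) -> dict[str, float]:
        """Snapshot of all five risks at grid time t."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"t={t} is not on the prediction grid")
        return {
            "t": float(self.times[i]),
            "h_pca": float(self.h_pca[i]),
            "h_npc": float(self.h_npc[i]),
            "r_om": float(self.r_om[i]),
            "r_pca": float(self.r_pca[i]),
            "r_npc": float(self.r_npc[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "h_pca": self.h_pca,
                "h_npc": self.h_npc,
                "r_om": self.r_om,
                "r_pca": self.r_pca,
                "r_npc": self.r_npc,
            }
        )


def _curves_from_pis(
    pi_pcsm: float, pi_npcm: float, model: PredictModel, grid: np.ndarray, scenario: str
) -> RiskPrediction:
    h_pca = marginal_risk_from_cumhaz(pi_pcsm, model.pcsm.baseline.cumhaz(grid))
    h_npc = marginal_risk_from_cumhaz(pi_npcm, model.npcm.baseline.cumhaz(grid))
    r_om, r_pca, r_npc = combine_competing_risks(h_pca, h_npc)
    return RiskPrediction(
        times=grid,
        h_pca=h_pca,
        h_npc=h_npc,
        r_om=r_om,
        r_pca=r_pca,
        r_npc=r_npc,
        pi_pcsm=float(pi_pcsm),
        pi_npcm=float(pi_npcm),
        scenario=scenario,
    )


def predict_curves(
    record: PatientRecord,
    model: PredictModel,
    grid: Sequence[float] | None = None,
    scenario: str | None = None,
) -> RiskPrediction:
    """Full competing-risk curves for one patient.

    ``scenario`` overrides the record's primary treatment (counterfactual
    prediction); the grid must lie within (0, 15] years and defaults to
    quarter-year steps through 15 years.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(grid > 15.0):
        raise ValueError("prediction grid must lie within (0, 15] years")
    label = scenario or record.treatment
    pi_p = prognostic_index(record, model, "pcsm", treatment_override=scenario)
    pi_n = prognostic_index(record, model, "npcm")
    return _curves_from_pis(pi_p, pi_n, model, grid, label)


@dataclass
class TreatmentBenefit:
    """Estimated benefit of radical treatment versus conservative management.

    ``os_gain`` is the absolute reduction in overall mortality risk at the
    horizon; ``pcsm_reduction`` the reduction in competing-risk-adjusted
    prostate-cancer mortality.  Competing risks guarantee
    os_gain <= pcsm_reduction.  ``band`` holds 15-year overall-survival
    values at treatment-efficacy fractions spanning 0-100% of the full
    log-hazard effect (f=0 reproduces the conservative curve).
    """

    horizon: float
    r_om_conservative: float
    r_om_radical: float
    os_gain: float
    pcsm_conservative: float
    pcsm_radical: float
    pcsm_reduction: float
    band: dict[float, float]
    band_curves: dict[float, pd.DataFrame] = field(repr=False, default_factory=dict)
    note: str | None = None


def treatment_benefit(
    record: PatientRecord,
    model: PredictModel,
    horizon: float = 15.0,
    efficacy_fractions: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> TreatmentBenefit:
    """Conservative-versus-radical benefit with a 0-100% efficacy band.

    The band scales the radical-treatment log-hazard ratio linearly by each
    fraction f — the proportional-hazards-consistent interpolation between no
    effect and the full data-derived effect.
    """
    if horizon not in (10.0, 15.0, 10, 15):
        raise ValueError("horizon must be 10 or 15 years")
    note = None
    if record.treatment == "hormone":
        note = (
            "record's primary treatment is hormone monotherapy; benefit is the "
            "counterfactual conservative-vs-radical comparison"
        )
        warnings.warn(note, stacklevel=2)
    grid = DEFAULT_GRID
    cons = predict_curves(record, model, grid, scenario="conservative")
    rad = predict_curves(record, model, grid, scenario="radical")
    treatment_term = model.pcsm.term_for("treatment")
    beta_radical = treatment_term.beta_for("radical")
    band: dict[float, float] = {}
    band_curves: dict[float, pd.DataFrame] = {}
    for f in efficacy_fractions:
        pred = _curves_from_pis(
            cons.pi_pcsm + f * beta_radical,
            cons.pi_npcm,
            model,
            grid,
            f"efficacy_{f:g}",
        )
        band[float(f)] = 1.0 - pred.at(horizon)["r_om"]
        band_curves[float(f)] = pred.to_frame()
    at_c = cons.at(horizon)
    at_r = rad.at(horizon)
    return TreatmentBenefit(
        horizon=float(horizon),
        r_om_conservative=at_c["r_om"],
        r_om_radical=at_r["r_om"],
        os_gain=at_c["r_om"] - at_r["r_om"],
        pcsm_conservative=at_c["r_pca"],
        pcsm_radical=at_r["r_pca"],
        pcsm_reduction=at_c["r_pca"] - at_r["r_pca"],
        band=band,
        band_curves=band_curves,
        note=note,
    )
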