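"""Calibration, discrimination and comparator risk-stratification scores.

Calibration compares observed with model-expected deaths in quintiles of
predicted risk (or arbitrary strata), integrating predictions over each
subject's own follow-up so short follow-up contributes its partial expected
risk; the May-Hosmer chi-square summarises agreement.  Discrimination is the
Harrell concordance index for right-censored data, with competing-cause
deaths censored at their death time for cause-specific indices, and
jackknife-based confidence intervals and paired model comparisons.

Comparators are the three international diagnosis-time stratification
systems: the UCSF-CAPRA point score, the three-tier EAU groups, and a
versioned NCCN ruleset including the >=50% positive-core criterion.  Where
T-stage subclassification is collapsed, stages 2 and 3 are taken as T2a and
T3a respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import PatientRecord, PredictModel
from .predict import cohort_risk_at

__all__ = [
    "CalibrationReport",
    "DiscriminationReport",
    "expected_events",
    "cohort_expected_events",
    "gof_test",
    "harrell_c",
    "calibration_quintiles",
    "capra_score",
    "eau_group",
    "nccn_group",
    "compare_discrimination",
    "EAU_ORDER",
    "NCCN_ORDER",
    "NCCN_RULESET_VERSION",
]

_CAUSE_COL = {"pcsm": "r_pca", "npcm": "r_npc", "om": "r_om"}
_CAUSE_EVENTS = {"pcsm": (1,), "npcm": (2,), "om": (1, 2)}


# ---------------------------------------------------------------------------
# calibration


def cohort_expected_events(
    model: PredictModel,
    df: pd.DataFrame,
    horizon: float,
    cause: str = "pcsm",
    basis: str = "hazard",
) -> np.ndarray:
    """Per-subject expected events, integrated over each subject's follow-up.

    ``basis='hazard'`` (default, the May-Hosmer construction): each subject
    contributes the cause-specific cumulative hazard exp(pi) Lambda0(t)
    accumulated over their own at-risk time min(follow-up, horizon) — any
    death or censoring ends the at-risk period.  Group sums of these have
    exactly the observed counts' expectation under a correct model, with
    Poisson-like variance, which is what makes the chi-square comparison
    well calibrated.

    ``basis='risk'``: each subject contributes the competing-risk-adjusted
    cumulative risk instead — a subject censored alive at c < horizon
    contributes the cause risk at c, while deaths (of either cause; the
    combined risks already account for competing death) and full follow-up
    contribute the horizon risk.  This reads directly as predicted deaths but
    is only approximately centred.

    Subjects with missing follow-up get NaN (callers report the exclusion
    count); zero follow-up contributes zero expected events.
    """
    from .predict import cohort_linear_predictor

    fu = pd.to_numeric(df["time_years"], errors="coerce").to_numpy(dtype=float)
    if basis == "hazard":
        t_eval = np.minimum(fu, horizon)
    elif basis == "risk":
        died = pd.to_numeric(df["event"], errors="coerce").to_numpy() > 0
        t_eval = np.where(died, horizon, np.minimum(fu, horizon))
    else:
        raise ValueError("basis must be 'hazard' or 'risk'")
    out = np.full(len(df), np.nan)
    ok = np.isfinite(t_eval)
    pos = ok & (t_eval > 0)
    if pos.any():
        sub = df.loc[pos]
        t = t_eval[pos]
        if basis == "hazard":
            cum = np.zeros(int(pos.sum()))
            for c in ("pcsm", "npcm") if cause == "om" else (cause,):
                pi = cohort_linear_predictor(sub, model, c)
                cum = cum + np.exp(pi) * model.cause_model(c).baseline.cumhaz(t)
            out[pos] = cum
        else:
            r_om, r_pca, r_npc = cohort_risk_at(sub, model, t)
            out[pos] = {"pcsm": r_pca, "npcm": r_npc, "om": r_om}[cause]
    out[ok & (t_eval <= 0)] = 0.0
    return out


def expected_events(
    predictions: Sequence,
    followup_times,
    horizon: float,
    cause: str = "pcsm",
    events=None,
) -> np.ndarray:
    """Expected events from stored prediction curves.

    ``predictions`` are :class:`~predictprostate.predict.RiskPrediction`
    objects (one per subject); each subject contributes the cause-specific
    cumulative risk interpolated at min(followup, horizon), the follow-up
    times being censoring times.  When the 0/1/2 ``events`` coding is
    supplied, subjects who died contribute the full horizon risk (see
    :func:`cohort_expected_events`).  Missing follow-up yields NaN.
    """
    col = _CAUSE_COL[cause]
    fu = np.asarray(followup_times, dtype=float)
    died = (
        np.zeros(len(fu), dtype=bool)
        if events is None
        else np.asarray(events) > 0
    )
    out = np.full(len(fu), np.nan)
    for i, (pred, t) in enumerate(zip(predictions, fu)):
        if not np.isfinite(t):
            continue
        te = horizon if died[i] else min(t, horizon)
        if te <= 0:
            out[i] = 0.0
            continue
        out[i] = float(np.interp(te, pred.times, getattr(pred, col)))
    return out


def gof_test(
    observed, expected, df_mode: str = "groups_minus_1"
) -> tuple[float, int, float]:
    """May-Hosmer goodness-of-fit chi-square over risk groups.

    chi2 = sum (O-E)^2 / E; degrees of freedom are G-1 by default
    (``df_mode='groups'`` uses G).  p below 0.05 suggests observed and
    expected event counts differ.
    """
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if len(O) < 2 or len(O) != len(E):
        raise ValueError("need matching observed/expected counts for >= 2 groups")
    if np.any(E <= 0):
        raise ValueError(
            "expected count of zero in a group; merge groups and retry"
        )
    chi2 = float(np.sum((O - E) ** 2 / E))
    df = len(O) - (1 if df_mode == "groups_minus_1" else 0)
    return chi2, df, float(sps.chi2.sf(chi2, df))


@dataclass
class CalibrationReport:
    """Observed vs expected deaths per risk group with the GOF summary."""

    cause: str
    horizon: float
    grouping: list[str]
    group_n: list[int]
    observed: list[float]
    expected: list[float]
    percent_difference: list[float]  # (O - E)/n * 100; observed excess positive
    chi2: float
    df: int
    p: float
    n_excluded_missing_followup: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.grouping,
                "n": self.group_n,
                "observed": self.observed,
                "expected": self.expected,
                "difference_pct": self.percent_difference,
            }
        )


def calibration_quintiles(
    model: PredictModel,
    cohort: pd.DataFrame,
    horizon: float = 10.0,
    cause: str = "pcsm",
    n_groups: int = 5,
    strata: str | None = None,
    df_mode: str = "groups",
    basis: str = "hazard",
) -> CalibrationReport:
    """Observed vs expected deaths within quintiles of predicted risk.

    ``strata`` switches from quintiles to grouping by an arbitrary cohort
    column (treatment, grade group, ...).  Expected counts integrate each
    subject's predicted outcome over their own follow-up on the stated
    ``basis`` (see :func:`cohort_expected_events`).
    """
    if len(cohort) < 50 and strata is None:
        raise ValueError("need >= 50 subjects for quintile calibration")
    e_i = cohort_expected_events(model, cohort, horizon, cause, basis=basis)
    keep = np.isfinite(e_i)
    n_excluded = int((~keep).sum())
    df = cohort.loc[keep].reset_index(drop=True)
    e_i = e_i[keep]
    fu = pd.to_numeric(df["time_years"], errors="coerce").to_numpy(dtype=float)
    ev = df["event"].to_numpy()
    observed_i = (np.isin(ev, _CAUSE_EVENTS[cause]) & (fu <= horizon)).astype(float)

    if strata is not None:
        labels = df[strata].astype(str)
        group_ids = labels
        group_names = sorted(labels.unique())
    else:
        r_om, r_pca, r_npc = cohort_risk_at(df, model, horizon)
        risk = {"pcsm": r_pca, "npcm": r_npc, "om": r_om}[cause]
        if np.allclose(risk, risk[0]):
            warnings.warn(
                "degenerate predictions (all equal); falling back to one group"
            )
            group_ids = pd.Series(["all"] * len(df))
            group_names = ["all"]
        else:
            q = pd.qcut(risk, n_groups, labels=False, duplicates="drop")
            group_ids = pd.Series(q).map(lambda g: f"Q{int(g) + 1}")
            group_names = sorted(group_ids.unique(), key=lambda s: int(s[1:]))

    O, E, N = [], [], []
    for g in group_names:
        m = (group_ids == g).to_numpy()
        O.append(float(observed_i[m].sum()))
        E.append(float(e_i[m].sum()))
        N.append(int(m.sum()))
    if len(O) >= 2:
        chi2, dof, p = gof_test(O, E, df_mode=df_mode)
    else:  # degenerate single-group fallback: no chi-square is defined
        chi2, dof, p = float("nan"), 0, float("nan")
    pct = [100.0 * (o - e) / n for o, e, n in zip(O, E, N)]
    return CalibrationReport(
        cause=cause,
        horizon=float(horizon),
        grouping=list(group_names),
        group_n=N,
        observed=O,
        expected=E,
        percent_difference=pct,
        chi2=chi2,
        df=dof,
        p=p,
        n_excluded_missing_followup=n_excluded,
    )


# ---------------------------------------------------------------------------
# discrimination


@dataclass
class DiscriminationReport:
    c_index: float
    ci_low: float
    ci_high: float
    se: float
    n_pairs: int
    cause: str
    horizon: float | None = None
    label: str = "model"
    _jackknife: np.ndarray | None = field(default=None, repr=False)


def _pair_counts(scores, times, events):
    """Per-subject concordant / comparable pair sums (vectorised, blocked).

    A pair is usable when the subject with the cause event has the shorter
    observed time (a censored subject tied in time with an event counts as
    surviving longer).  Tied scores contribute 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    n = len(s)
    conc_i = np.zeros(n)
    comp_i = np.zeros(n)
    block = max(1, int(4e6 // max(n, 1)))
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        ti = t[sl][:, None]
        si = s[sl][:, None]
        ei = e[sl][:, None]
        usable = ei & ((ti < t[None, :]) | ((ti == t[None, :]) & ~e[None, :]))
        conc = usable * ((si > s[None, :]) + 0.5 * (si == s[None, :]))
        comp_block = usable.sum(axis=1)
        conc_block = conc.sum(axis=1)
        conc_i[sl] += conc_block
        comp_i[sl] += comp_block
        # symmetric contribution to the later member of each pair
        conc_i += conc.sum(axis=0)
        comp_i += usable.sum(axis=0)
    return conc_i, comp_i


def harrell_c(
    scores,
    times,
    events,
    cause: int | str = 1,
    label: str = "model",
    horizon: float | None = None,
) -> DiscriminationReport:
    """Harrell concordance index for right-censored, cause-specific outcomes.

    ``events`` uses the cohort coding (0 censored, 1 PCa death, 2 other);
    deaths from the competing cause are censored at their death time.  The
    confidence interval comes from a leave-one-subject-out jackknife.
    """
    if isinstance(cause, str) and not cause.isdigit():
        code = {"pcsm": (1,), "npcm": (2,), "om": (1, 2)}[cause]
    else:
        code = (int(cause),)
    e = np.isin(np.asarray(events), code)
    conc_i, comp_i = _pair_counts(scores, times, e)
    # each usable ordered pair was counted once for each member
    total_conc = conc_i.sum() / 2.0
    total_comp = comp_i.sum() / 2.0
    if total_comp == 0:
        raise ValueError("no usable pairs for the concordance index")
    c = total_conc / total_comp
    n = len(conc_i)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = np.where(
            total_comp - comp_i > 0,
            (total_conc - conc_i) / (total_comp - comp_i),
            c,
        )
    se = float(np.sqrt((n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)))
    return DiscriminationReport(
        c_index=float(c),
        ci_low=float(max(0.0, c - 1.96 * se)),
        ci_high=float(min(1.0, c + 1.96 * se)),
        se=se,
        n_pairs=int(round(total_comp)),
        cause=str(cause),
        horizon=horizon,
        label=label,
        _jackknife=c_loo,
    )


def compare_discrimination(
    score_sets: Mapping[str, Sequence[float]],
    times,
    events,
    cause: int | str = 1,
) -> pd.DataFrame:
    """C-index per model with pairwise jackknife p-values against the first.

    All score sets must cover the same subjects in the same order.
    """
    if len(score_sets) < 2:
        raise ValueError("need at least two score sets to compare")
    lengths = {len(v) for v in score_sets.values()}
    if len(lengths) != 1:
        raise ValueError("score sets are misaligned (different lengths)")
    reports = {
        name: harrell_c(s, times, events, cause=cause, label=name)
        for name, s in score_sets.items()
    }
    names = list(reports)
    ref = names[0]
    rows = []
    n = lengths.pop()
    for name in names:
        rep = reports[name]
        if name == ref:
            p = None
            diff = 0.0
        else:
            d_loo = reports[ref]._jackknife - rep._jackknife
            diff = reports[ref].c_index - rep.c_index
            se_d = float(
                np.sqrt((n - 1) / n * np.sum((d_loo - d_loo.mean()) ** 2))
            )
            if se_d == 0:
                p = 1.0
            else:
                p = float(2.0 * sps.norm.sf(abs(diff) / se_d))
        rows.append(
            {
                "model": name,
                "c_index": rep.c_index,
                "ci_low": rep.ci_low,
                "ci_high": rep.ci_high,
                "diff_vs_" + ref: diff,
                "p_vs_" + ref: p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# comparator scores

EAU_ORDER = ("low", "intermediate", "high")

NCCN_RULESET_VERSION = "post-2018 (includes >=50% positive-core criterion)"
NCCN_ORDER = (
    "low",
    "favourable_intermediate",
    "unfavourable_intermediate",
    "high",
    "very_high",
)


def _require(record: PatientRecord, fields: Sequence[str]) -> None:
    missing = [f for f in fields if getattr(record, f) is None]
    if missing:
        raise ValueError(f"missing component(s) for risk score: {', '.join(missing)}")


# grade group -> (primary, secondary) Gleason pattern representative
_GG_GLEASON = {1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}


def capra_score(record: PatientRecord) -> int:
    """UCSF-CAPRA points (0-10) from diagnostic information.

    Age (<50: 0, >=50: 1), PSA bands (<=6: 0, >6-10: 1, >10-20: 2,
    >20-30: 3, >30: 4), Gleason-pattern points mapped from grade group
    (no pattern 4/5: 0, secondary 4/5: 1, primary 4/5: 3), T-stage
    (T1/T2: 0, T3+: 1) and >=34% positive cores (1 point).  Missing core
    counts contribute 0 points (no imputation), matching complete-case use.
    """
    _require(record, ["age", "psa", "grade_group", "t_stage"])
    pts = 0
    pts += 0 if record.age < 50 else 1
    psa = record.psa
    if psa <= 6:
        pts += 0
    elif psa <= 10:
        pts += 1
    elif psa <= 20:
        pts += 2
    elif psa <= 30:
        pts += 3
    else:
        pts += 4
    primary, secondary = _GG_GLEASON[record.grade_group]
    if primary >= 4:
        pts += 3
    elif secondary >= 4:
        pts += 1
    pts += 0 if record.t_stage <= 2 else 1
    frac = record.ppc_fraction()
    if frac is not None and frac >= 0.34:
        pts += 1
    return pts


def eau_group(record: PatientRecord) -> str:
    """Three-tier EAU risk group.

    Collapsed stages follow the stated convention T2 -> T2a, T3 -> T3a; so a
    recorded T2 never reaches the high-risk >=T2c criterion, while T3/T4 are
    locally advanced (high).  Low: PSA < 10 and grade group 1 and T1-T2a;
    high: PSA > 20 or grade group 4-5 or T3-T4; else intermediate.
    """
    _require(record, ["psa", "grade_group", "t_stage"])
    if record.psa > 20 or record.grade_group >= 4 or record.t_stage >= 3:
        return "high"
    if record.psa < 10 and record.grade_group == 1 and record.t_stage <= 2:
        return "low"
    return "intermediate"


def nccn_group(record: PatientRecord) -> str:
    """NCCN risk category under the versioned post-2018 ruleset.

    Very high: T4.  High: T3 (taken as T3a), grade group 4-5, or PSA > 20.
    Low: grade group 1, PSA < 10, T1-T2 (taken as T2a); the very-low tier is
    folded into low because PSA density and per-core details are not
    recorded.  Intermediate splits on risk factors (PSA 10-20, grade group
    2-3): favourable = one factor, grade group 1-2 and < 50% positive cores;
    otherwise unfavourable (including >= 50% cores, the criterion added in
    the ruleset version pinned here).
    """
    _require(record, ["psa", "grade_group", "t_stage"])
    if record.t_stage >= 4:
        return "very_high"
    if record.t_stage == 3 or record.grade_group >= 4 or record.psa > 20:
        return "high"
    if record.grade_group == 1 and record.psa < 10 and record.t_stage <= 2:
        return "low"
    n_irf = int(10 <= record.psa <= 20) + int(record.grade_group in (2, 3))
    frac = record.ppc_fraction()
    ge50 = frac is not None and frac >= 0.5
    if n_irf <= 1 and record.grade_group <= 2 and not ge50:
        return "favourable_intermediate"
    return "unfavourable_intermediate"


def comparator_scores(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """CAPRA points plus ordinal EAU/NCCN tiers for a record list."""
    return pd.DataFrame(
        {
            "capra": [capra_score(r) for r in records],
            "eau": [EAU_ORDER.index(eau_group(r)) for r in records],
            "nccn": [NCCN_ORDER.index(nccn_group(r)) for r in records],
        }
    )
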