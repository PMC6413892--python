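"""End-to-end model development on any compliant cohort.

Reproduces the published model-building procedure: a seeded 70:30
development/validation split; cause-specific Cox fits (Efron ties) treating
the competing cause as censoring; backwards elimination at a 5% level with
multi-df Wald tests for factors; multivariable-fractional-polynomial form
selection for continuous covariates; Breslow estimation and FP smoothing of
each cumulative baseline hazard; and the offset-based biopsy-core (PPC)
extension with coding selection by likelihood ratio, AIC and BIC.

The fitting surface is exposed both as plain functions and as sklearn-style
estimators (`CauseSpecificCoxFP`, `PredictModelBuilder`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .fp import DEFAULT_POWER_SET, select_fp, smooth_baseline
from .model import (
    CategoricalTerm,
    CauseSpecificModel,
    FPBaseline,
    FPTerm,
    PredictModel,
)

__all__ = [
    "VariableSpec",
    "PipelineConfig",
    "FitReport",
    "PPCExtensionReport",
    "split_cohort",
    "censor_at",
    "fit_cause_model",
    "estimate_baseline",
    "build_model",
    "fit_ppc_extension",
    "CauseSpecificCoxFP",
    "PredictModelBuilder",
    "default_candidates",
    "published_structure_candidates",
]

_EVENT_CODE = {"pcsm": 1, "npcm": 2}


@dataclass
class VariableSpec:
    """One candidate predictor and how it enters the model.

    kind='fp' continuous with FP form (searched unless ``fixed_term`` pins
    it); kind='factor' categorical with the stated reference and level order;
    kind='binary' a 0/1 indicator.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    reference: str | None = None
    pre_shift: float = 0.0
    pre_scale: float = 1.0
    fixed_term: FPTerm | None = None


def default_candidates(cause: str) -> list[VariableSpec]:
    """The candidate predictor sets entered into each cause-specific model."""
    if cause == "pcsm":
        return [
            VariableSpec("age", "fp", pre_scale=10.0),
            VariableSpec("psa", "fp", pre_shift=1.0, pre_scale=100.0),
            VariableSpec(
                "grade_group", "factor", levels=("1", "2", "3", "4", "5"), reference="1"
            ),
            VariableSpec(
                "t_stage", "factor", levels=("1", "2", "3", "4"), reference="1"
            ),
            VariableSpec(
                "treatment",
                "factor",
                levels=("conservative", "radical", "hormone"),
                reference="conservative",
            ),
            VariableSpec("comorbidity", "binary"),
        ]
    if cause == "npcm":
        return [
            VariableSpec("age", "fp"),
            VariableSpec("comorbidity", "binary"),
        ]
    raise ValueError(f"unknown cause {cause!r}")


def published_structure_candidates(cause: str) -> list[VariableSpec]:
    """Candidates with the published FP forms pinned (no search/elimination).

    Used when refitting the published model structure on new data: age and
    PSA enter through the printed transforms, all factors as printed.
    """
    from .defaults import build_published_model

    model = build_published_model()
    cm = model.cause_model(cause)
    specs = default_candidates(cause)
    for spec in specs:
        if spec.kind == "fp":
            term = cm.term_for(spec.name)
            spec.fixed_term = term
            spec.pre_shift = term.pre_shift
            spec.pre_scale = term.pre_scale
    if cause == "pcsm":
        specs = [s for s in specs if s.name != "comorbidity"]
    return specs


def split_cohort(
    cohort: pd.DataFrame, ratio: float = 0.7, seed: int = 20251201
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random development/validation split (sizes floor(n*ratio) and
    the remainder); disjoint and exhaustive."""
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_dev = int(np.floor(n * ratio))
    dev = cohort.iloc[perm[:n_dev]].reset_index(drop=True)
    val = cohort.iloc[perm[n_dev:]].reset_index(drop=True)
    return dev, val


def censor_at(df: pd.DataFrame, horizon: float = 15.0) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` years."""
    out = df.copy()
    over = out["time_years"] > horizon
    out.loc[over, "time_years"] = horizon
    out.loc[over, "event"] = 0
    return out


# ---------------------------------------------------------------------------
# design-matrix construction


def _factor_levels(values) -> list[str]:
    return [str(v) for v in values]


def _level_key(v) -> str:
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)) and float(v).is_integer():
        return str(int(v))
    return str(v)


def _design_for(
    df: pd.DataFrame, spec: VariableSpec, term: FPTerm | None
) -> tuple[np.ndarray, list[str]]:
    """Design columns and their names for one variable."""
    if spec.kind == "fp":
        x = df[spec.name].to_numpy(dtype=float)
        basis = term.basis(x)
        names = [f"{spec.name}_fp{j}" for j in range(basis.shape[-1])]
        return np.atleast_2d(basis.reshape(len(df), -1)), names
    if spec.kind == "factor":
        vals = [_level_key(v) for v in df[spec.name]]
        cols, names = [], []
        for level in spec.levels:
            if level == spec.reference:
                continue
            cols.append(np.asarray([v == level for v in vals], dtype=float))
            names.append(f"{spec.name}[{level}]")
        return np.column_stack(cols), names
    if spec.kind == "binary":
        return (
            df[spec.name].to_numpy(dtype=float).reshape(-1, 1),
            [spec.name],
        )
    raise ValueError(f"unknown variable kind {spec.kind!r}")


def _build_design(
    df: pd.DataFrame,
    specs: Sequence[VariableSpec],
    terms: Mapping[str, FPTerm],
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    blocks, names, groups = [], [], {}
    col = 0
    for spec in specs:
        X, nm = _design_for(df, spec, terms.get(spec.name))
        blocks.append(X)
        names.extend(nm)
        groups[spec.name] = list(range(col, col + X.shape[1]))
        col += X.shape[1]
    return np.column_stack(blocks), names, groups


def _phreg_fit(time, status, X, offset=None):
    from statsmodels.duration.hazard_regression import PHReg

    from .fp import _ties_mode

    model = PHReg(time, X, status=status, ties=_ties_mode(time, status), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    return res


def _wald_group_p(params, cov, idx) -> float:
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return 1.0
    return float(sps.chi2.sf(chi2, len(idx)))


def _schoenfeld_ph_pvalues(
    time, status, X, params, names
) -> dict[str, float]:
    """Correlation of Schoenfeld residuals with event time, per column.

    A small p suggests a time-varying effect (proportional-hazards
    violation) for that column.
    """
    time = np.asarray(time, float)
    status = np.asarray(status, bool)
    order = np.argsort(-time, kind="stable")  # descending time
    Xs = X[order]
    lp = Xs @ params
    w = np.exp(lp)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * Xs, axis=0)
    is_event = status[order]
    xbar = s1 / s0[:, None]
    resid = Xs[is_event] - xbar[is_event]
    t_event = time[order][is_event]
    out = {}
    for j, name in enumerate(names):
        if len(t_event) < 3 or np.std(resid[:, j]) == 0:
            out[name] = 1.0
            continue
        r, p = sps.pearsonr(resid[:, j], t_event)
        out[name] = float(p)
    return out


@dataclass
class FitReport:
    """Everything a reader needs to audit one cause-specific fit."""

    cause: str
    n: int
    n_events: int
    retained: dict[str, dict] = field(default_factory=dict)
    eliminated: list[tuple[str, float]] = field(default_factory=list)
    fp_powers: dict[str, tuple[float, ...]] = field(default_factory=dict)
    ph_pvalues: dict[str, float] = field(default_factory=dict)
    coef_names: list[str] = field(default_factory=list)
    coefs: dict[str, float] = field(default_factory=dict)
    ses: dict[str, float] = field(default_factory=dict)
    baseline_r_squared: float | None = None


def _initial_term(df: pd.DataFrame, spec: VariableSpec) -> FPTerm:
    x = df[spec.name].to_numpy(dtype=float)
    z = (x + spec.pre_shift) / spec.pre_scale
    return FPTerm(
        variable=spec.name,
        powers=(1.0,),
        betas=(0.0,),
        pre_shift=spec.pre_shift,
        pre_scale=spec.pre_scale,
        centers=(float(np.mean(z)),),
    )


def _term_from_fpfit(df: pd.DataFrame, spec: VariableSpec, fit) -> FPTerm:
    """Centered FPTerm from a selection result (centers = dev-sample means)."""
    x = df[spec.name].to_numpy(dtype=float)
    raw = FPTerm(
        variable=spec.name,
        powers=fit.powers,
        betas=fit.betas,
        pre_shift=spec.pre_shift,
        pre_scale=spec.pre_scale,
        centers=(0.0,) * len(fit.powers),
    )
    centers = tuple(float(c) for c in raw.basis(x).reshape(len(df), -1).mean(axis=0))
    return FPTerm(
        variable=spec.name,
        powers=fit.powers,
        betas=fit.betas,
        pre_shift=spec.pre_shift,
        pre_scale=spec.pre_scale,
        centers=centers,
    )


def fit_cause_model(
    dev: pd.DataFrame,
    cause: str,
    candidates: Sequence[VariableSpec] | None = None,
    alpha: float = 0.05,
    fp_search: bool = True,
    backward: bool = True,
    power_set: tuple[float, ...] = DEFAULT_POWER_SET,
) -> tuple[CauseSpecificModel, FitReport]:
    """Cause-specific proportional-hazards fit with MFP and elimination.

    The competing cause is treated as censoring at its death time.  Backwards
    elimination removes the variable with the largest multi-df Wald p-value
    each round while it exceeds ``alpha``; FP forms are re-selected after
    each structural change.  Returns a coefficients-only model (baseline is
    estimated separately) and a full report.
    """
    df = censor_at(dev)
    time = df["time_years"].to_numpy(dtype=float)
    status = (df["event"].to_numpy() == _EVENT_CODE[cause]).astype(int)
    if status.sum() == 0:
        raise ValueError(f"cohort has zero events for cause {cause!r}")
    specs = list(candidates) if candidates is not None else default_candidates(cause)

    terms: dict[str, FPTerm] = {}
    for spec in specs:
        if spec.kind == "fp":
            terms[spec.name] = (
                spec.fixed_term if spec.fixed_term is not None else _initial_term(df, spec)
            )

    def reselect_fp(active: list[VariableSpec]) -> None:
        for spec in active:
            if spec.kind != "fp" or spec.fixed_term is not None:
                continue
            others = [s for s in active if s.name != spec.name]
            adj, _, _ = (
                _build_design(df, others, terms) if others else (None, [], {})
            )
            fit = select_fp(
                time,
                status,
                df[spec.name].to_numpy(dtype=float),
                variable=spec.name,
                adjusters=adj,
                alpha=alpha,
                power_set=power_set,
                pre_shift=spec.pre_shift,
                pre_scale=spec.pre_scale,
            )
            if fit.powers is not None:
                terms[spec.name] = _term_from_fpfit(df, spec, fit)
            # a null FP fit leaves the current (simplest) form in place for
            # the Wald elimination step to act on

    report = FitReport(cause=cause, n=len(df), n_events=int(status.sum()))
    active = list(specs)
    if fp_search:
        reselect_fp(active)

    while True:
        X, names, groups = _build_design(df, active, terms)
        # flag factor levels with zero events
        for spec in active:
            if spec.kind == "factor":
                for level in spec.levels:
                    mask = [
                        _level_key(v) == level for v in df[spec.name]
                    ]
                    if status[np.asarray(mask)].sum() == 0:
                        warnings.warn(
                            f"no {cause} events at level {level!r} of "
                            f"{spec.name!r}; coefficient will be unstable"
                        )
        res = _phreg_fit(time, status, X)
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not backward:
            break
        pvals = {
            spec.name: _wald_group_p(params, cov, groups[spec.name])
            for spec in active
        }
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha or len(active) == 1:
            break
        report.eliminated.append((worst, float(pvals[worst])))
        active = [s for s in active if s.name != worst]
        if fp_search:
            reselect_fp(active)

    bse = np.asarray(res.bse)
    report.coef_names = names
    report.coefs = {n: float(b) for n, b in zip(names, params)}
    report.ses = {n: float(s) for n, s in zip(names, bse)}
    for spec in active:
        idx = groups[spec.name]
        report.retained[spec.name] = {
            "betas": {names[i]: float(params[i]) for i in idx},
            "ses": {names[i]: float(bse[i]) for i in idx},
            "p": _wald_group_p(params, cov, idx),
        }
        if spec.kind == "fp":
            report.fp_powers[spec.name] = terms[spec.name].powers
    report.ph_pvalues = _schoenfeld_ph_pvalues(time, status, X, params, names)

    fp_terms, cat_terms = [], []
    for spec in active:
        idx = groups[spec.name]
        if spec.kind == "fp":
            t = terms[spec.name]
            fp_terms.append(
                FPTerm(
                    variable=t.variable,
                    powers=t.powers,
                    betas=tuple(float(params[i]) for i in idx),
                    pre_shift=t.pre_shift,
                    pre_scale=t.pre_scale,
                    centers=t.centers,
                )
            )
        elif spec.kind == "factor":
            betas = {spec.reference: 0.0}
            for i, level in zip(idx, [l for l in spec.levels if l != spec.reference]):
                betas[level] = float(params[i])
            cat_terms.append(CategoricalTerm(spec.name, spec.reference, betas))
        else:  # binary
            cat_terms.append(
                CategoricalTerm(
                    spec.name, "0", {"0": 0.0, "1": float(params[idx[0]])}
                )
            )
    model = CauseSpecificModel(
        cause=cause,
        fp_terms=tuple(fp_terms),
        categorical_terms=tuple(cat_terms),
        baseline=None,
    )
    return model, report


def cause_linear_predictor(df: pd.DataFrame, cm: CauseSpecificModel) -> np.ndarray:
    """Centered linear predictor of a single cause-specific model."""
    pi = np.zeros(len(df))
    for term in cm.fp_terms:
        pi = pi + term.contribution(df[term.variable].to_numpy(dtype=float))
    for cat in cm.categorical_terms:
        pi = pi + np.asarray([cat.beta_for(_level_key(v)) for v in df[cat.variable]])
    return pi


def estimate_baseline(
    model: CauseSpecificModel, dev: pd.DataFrame, cause: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow cumulative baseline hazard at the centered configuration.

    Returns the nondecreasing step function (event times, cumulative hazard).
    """
    cause = cause or model.cause
    df = censor_at(dev)
    time = df["time_years"].to_numpy(dtype=float)
    status = (df["event"].to_numpy() == _EVENT_CODE[cause]).astype(int)
    if status.sum() == 0:
        raise ValueError(f"no events for cause {cause!r}")
    lp = cause_linear_predictor(df, model)
    w = np.exp(lp)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    s_sorted = status[order]
    w_sorted = w[order]
    # risk-set sums: total weight of subjects with time >= t
    at_risk = np.cumsum(w_sorted[::-1])[::-1]
    event_times, inverse = np.unique(t_sorted[s_sorted == 1], return_inverse=True)
    increments = np.zeros(len(event_times))
    # first index with each event time (sorted) gives the risk-set sum
    idx_first = np.searchsorted(t_sorted, event_times, side="left")
    d = np.bincount(inverse, minlength=len(event_times))
    increments = d / at_risk[idx_first]
    return event_times, np.cumsum(increments)


@dataclass
class PipelineConfig:
    """All knobs of the development pipeline; every stochastic step is seeded."""

    alpha: float = 0.05
    split_ratio: float = 0.7
    seed: int = 20251201
    power_set: tuple[float, ...] = DEFAULT_POWER_SET
    fp_search: bool = True
    backward: bool = True
    use_split: bool = True
    candidates_pcsm: Sequence[VariableSpec] | None = None
    candidates_npcm: Sequence[VariableSpec] | None = None


def build_model(
    cohort: pd.DataFrame, config: PipelineConfig | None = None
) -> tuple[PredictModel, dict[str, FitReport]]:
    """Split, fit both causes, estimate and smooth baselines.

    Deterministic given the seed in ``config``.
    """
    config = config or PipelineConfig()
    cohort = censor_at(cohort)
    if config.use_split:
        dev, _val = split_cohort(cohort, config.split_ratio, config.seed)
    else:
        dev = cohort
    reports: dict[str, FitReport] = {}
    cause_models: dict[str, CauseSpecificModel] = {}
    for cause, cands in (
        ("pcsm", config.candidates_pcsm),
        ("npcm", config.candidates_npcm),
    ):
        cm, rep = fit_cause_model(
            dev,
            cause,
            candidates=cands,
            alpha=config.alpha,
            fp_search=config.fp_search,
            backward=config.backward,
            power_set=config.power_set,
        )
        times, cumhaz = estimate_baseline(cm, dev, cause)
        baseline = smooth_baseline(
            times, cumhaz, power_set=config.power_set, alpha=config.alpha
        )
        rep.baseline_r_squared = baseline.r_squared
        cause_models[cause] = CauseSpecificModel(
            cause=cause,
            fp_terms=cm.fp_terms,
            categorical_terms=cm.categorical_terms,
            baseline=baseline,
        )
        reports[cause] = rep
    comorb = pd.to_numeric(dev.get("comorbidity"), errors="coerce")
    metadata = {
        "seed": config.seed,
        "alpha": config.alpha,
        "power_set": list(config.power_set),
        "n_development": int(len(dev)),
        "comorbidity_prevalence": float(np.nanmean(comorb))
        if comorb is not None and np.isfinite(np.nanmean(comorb))
        else 0.1021,
        "version": "refit",
    }
    model = PredictModel(
        pcsm=cause_models["pcsm"],
        npcm=cause_models["npcm"],
        ppc_hr=None,
        metadata=metadata,
    )
    return model, reports


@dataclass
class PPCExtensionReport:
    """Selection record for the biopsy percent-positive-cores extension."""

    candidates: dict[str, dict] = field(default_factory=dict)
    selected: str = ""
    beta: float = float("nan")
    se: float = float("nan")
    lr_p: float = float("nan")
    p_ge50: float = float("nan")
    multipliers: dict[str, float] = field(default_factory=dict)
    note: str | None = None


def fit_ppc_extension(
    subcohort: pd.DataFrame, base_model: PredictModel, alpha: float = 0.05
) -> tuple[dict[str, float], PPCExtensionReport]:
    """Offset fit of biopsy core involvement against PCSM.

    The base prognostic index enters as a fixed offset, so base-model
    coefficients are untouched by construction.  Candidate codings of the
    positive-core fraction (continuous, dichotomised at 50%, tertiles) are
    compared by likelihood-ratio test, AIC and BIC; ties go to the simplest
    coding.  The selected dichotomous contrast is weight-adjusted so the
    sub-cohort-average multiplier is 1, and unknown PPC maps to exactly 1.0.
    """
    from .predict import cohort_linear_predictor

    df = censor_at(subcohort)
    cp = pd.to_numeric(df["cores_positive"], errors="coerce")
    ct = pd.to_numeric(df["cores_total"], errors="coerce")
    frac = (cp / ct).to_numpy(dtype=float)
    known = np.isfinite(frac)
    if not known.any():
        raise ValueError("all PPC values are missing in the sub-cohort")
    df = df.loc[known].reset_index(drop=True)
    frac = frac[known]
    time = df["time_years"].to_numpy(dtype=float)
    status = (df["event"].to_numpy() == 1).astype(int)
    offset = cohort_linear_predictor(df, base_model, "pcsm", include_ppc=False)

    ge50 = (frac >= 0.5).astype(float)
    codings = {
        "dichotomous_50": ge50.reshape(-1, 1),
        "continuous": frac.reshape(-1, 1),
        "tertiles": np.column_stack(
            [(frac >= 1 / 3) & (frac < 2 / 3), frac >= 2 / 3]
        ).astype(float),
    }
    complexity = {"dichotomous_50": 0, "continuous": 1, "tertiles": 2}

    from statsmodels.duration.hazard_regression import PHReg

    from .fp import _ties_mode

    ties = _ties_mode(time, status)
    report = PPCExtensionReport()
    results = {}
    for name, X in codings.items():
        model = PHReg(time, X, status=status, ties=ties, offset=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=False)
        k = X.shape[1]
        llf = float(res.llf)
        llf0 = float(model.loglike(np.zeros(k)))
        lr = 2.0 * (llf - llf0)
        report.candidates[name] = {
            "df": k,
            "loglik": llf,
            "lr_chi2": lr,
            "lr_p": float(sps.chi2.sf(max(lr, 0.0), k)),
            "aic": 2 * k - 2 * llf,
            "bic": k * np.log(max(status.sum(), 1)) - 2 * llf,
        }
        results[name] = res

    by_aic = min(report.candidates, key=lambda n: report.candidates[n]["aic"])
    by_bic = min(report.candidates, key=lambda n: report.candidates[n]["bic"])
    if by_aic == by_bic:
        selected = by_aic
    else:  # disagreement: the simpler of the two front-runners
        selected = min((by_aic, by_bic), key=lambda n: complexity[n])
        report.note = f"AIC chose {by_aic}, BIC chose {by_bic}; took the simpler"
    report.selected = selected

    res_d = results["dichotomous_50"]
    beta = float(np.asarray(res_d.params)[0])
    report.beta = beta
    report.se = float(np.asarray(res_d.bse)[0])
    report.lr_p = report.candidates[selected]["lr_p"]
    p_ge = float(ge50.mean())
    report.p_ge50 = p_ge
    # weight adjustment: centre so the sub-cohort mean multiplier is 1
    delta = -np.log((1.0 - p_ge) + p_ge * np.exp(beta))
    multipliers = {
        "lt50": float(np.exp(delta)),
        "ge50": float(np.exp(delta + beta)),
        "unknown": 1.0,
    }
    if selected != "dichotomous_50" and report.note is None:
        report.note = (
            f"selected coding was {selected}; shipped multipliers use the "
            "dichotomous contrast"
        )
    report.multipliers = multipliers
    return multipliers, report


# ---------------------------------------------------------------------------
# sklearn-style estimator surface


class CauseSpecificCoxFP(BaseEstimator):
    """One cause-specific Cox model with MFP selection, as an estimator.

    ``fit`` expects the canonical cohort DataFrame (with ``time_years`` and
    0/1/2-coded ``event``); ``predict`` returns the centered linear
    predictor.  Fitted attributes: ``model_`` (CauseSpecificModel),
    ``report_`` (FitReport).
    """

    def __init__(
        self,
        cause: str = "pcsm",
        alpha: float = 0.05,
        fp_search: bool = True,
        backward: bool = True,
        power_set: tuple[float, ...] = DEFAULT_POWER_SET,
        candidates: Sequence[VariableSpec] | None = None,
    ):
        self.cause = cause
        self.alpha = alpha
        self.fp_search = fp_search
        self.backward = backward
        self.power_set = power_set
        self.candidates = candidates

    def fit(self, X: pd.DataFrame, y=None):
        self.model_, self.report_ = fit_cause_model(
            X,
            self.cause,
            candidates=self.candidates,
            alpha=self.alpha,
            fp_search=self.fp_search,
            backward=self.backward,
            power_set=self.power_set,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return cause_linear_predictor(X, self.model_)


class PredictModelBuilder(BaseEstimator):
    """The full development pipeline as an estimator.

    ``fit`` runs split -> cause-specific fits -> baseline estimation and
    smoothing; ``predict`` returns competing-risk-adjusted cumulative risk at
    ``horizon`` for the requested cause.  Fitted attributes: ``model_``
    (PredictModel) and ``reports_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        split_ratio: float = 0.7,
        seed: int = 20251201,
        power_set: tuple[float, ...] = DEFAULT_POWER_SET,
        fp_search: bool = True,
        backward: bool = True,
        use_split: bool = True,
    ):
        self.alpha = alpha
        self.split_ratio = split_ratio
        self.seed = seed
        self.power_set = power_set
        self.fp_search = fp_search
        self.backward = backward
        self.use_split = use_split

    def fit(self, X: pd.DataFrame, y=None):
        config = PipelineConfig(
            alpha=self.alpha,
            split_ratio=self.split_ratio,
            seed=self.seed,
            power_set=self.power_set,
            fp_search=self.fp_search,
            backward=self.backward,
            use_split=self.use_split,
        )
        self.model_, self.reports_ = build_model(X, config)
        return self

    def predict(
        self, X: pd.DataFrame, horizon: float = 15.0, cause: str = "pcsm"
    ) -> np.ndarray:
        from .predict import cohort_risk_at

        r_om, r_pca, r_npc = cohort_risk_at(X, self.model_, horizon)
        return {"om": r_om, "pcsm": r_pca, "npcm": r_npc}[cause]
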