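"""Fractional-polynomial fitting: covariate transform selection and
baseline-hazard smoothing.

An FP1 transform is x**p for one power p from a small admissible set (0
denoting ln x); an FP2 transform combines two powers, with the repeated-power
convention x**p and x**p * ln x.  The function-selection procedure is the
standard closed test: best FP2 against the null (4 df), against linear
(3 df), and against best FP1 (2 df), descending in complexity at a fixed
significance level, returning the simplest adequate form.

The same machinery smooths a nonparametric step cumulative baseline hazard by
regressing its logarithm on an FP function of time, giving an evaluable
baseline for risk prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy import stats as sps

from .model import FPBaseline, FPTerm, _fp_basis

__all__ = [
    "DEFAULT_POWER_SET",
    "FPFit",
    "fp1_fp2_candidates",
    "select_fp",
    "smooth_baseline",
]

DEFAULT_POWER_SET: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def fp1_fp2_candidates(
    power_set: tuple[float, ...] = DEFAULT_POWER_SET,
) -> list[tuple[float, ...]]:
    """All FP1 singletons and unordered FP2 pairs (repeats included).

    For m powers this is m + m(m+1)/2 candidates.
    """
    powers = tuple(power_set)
    if len(powers) == 0:
        raise ValueError("power set must be non-empty")
    fp1 = [(p,) for p in powers]
    fp2 = [tuple(sorted(c)) for c in combinations_with_replacement(powers, 2)]
    return fp1 + fp2


@dataclass
class FPFit:
    """Outcome of the FP function-selection closed test for one variable."""

    variable: str
    powers: tuple[float, ...] | None  # None => variable not significant
    betas: tuple[float, ...]
    pre_shift: float
    pre_scale: float
    deviance: float
    competitor_deviances: dict[str, float] = field(default_factory=dict)
    closed_test_pvalues: dict[str, float] = field(default_factory=dict)

    def to_term(self, centers: tuple[float, ...] | None = None) -> FPTerm:
        if self.powers is None:
            raise ValueError("variable was eliminated; no term to build")
        centers = centers if centers is not None else (0.0,) * len(self.powers)
        return FPTerm(
            variable=self.variable,
            powers=self.powers,
            betas=self.betas,
            pre_shift=self.pre_shift,
            pre_scale=self.pre_scale,
            centers=centers,
        )


def _ties_mode(time, status) -> str:
    """Efron's correction when tied event times exist; plain Breslow when
    times are distinct (the two coincide there, Breslow is cheaper)."""
    et = np.asarray(time)[np.asarray(status, bool)]
    return "efron" if len(et) != len(np.unique(et)) else "breslow"


def _cox_llf(time, status, X, offset=None):
    """Partial log-likelihood of a Cox fit (Efron ties); (llf, params)."""
    from statsmodels.duration.hazard_regression import PHReg

    model = PHReg(time, X, status=status, ties=_ties_mode(time, status), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    return float(res.llf), np.asarray(res.params)


def _null_llf(time, status, adjusters, offset=None):
    from statsmodels.duration.hazard_regression import PHReg

    if adjusters is not None and adjusters.shape[1] > 0:
        return _cox_llf(time, status, adjusters, offset)[0]
    # no adjusters: evaluate the partial likelihood at beta = 0
    dummy = np.ones((len(time), 1))
    model = PHReg(
        time, dummy, status=status, ties=_ties_mode(time, status), offset=offset
    )
    return float(model.loglike(np.zeros(1)))


def select_fp(
    time,
    status,
    x,
    variable: str = "x",
    adjusters: np.ndarray | None = None,
    alpha: float = 0.05,
    power_set: tuple[float, ...] = DEFAULT_POWER_SET,
    pre_shift: float = 0.0,
    pre_scale: float = 1.0,
    min_events: int = 50,
) -> FPFit:
    """Closed-test FP selection for one continuous covariate in a Cox model.

    ``adjusters`` are design columns held fixed during the search.  Returns
    the simplest adequate form; ``powers=None`` means the variable showed no
    effect at level ``alpha`` (candidate for elimination).  Deterministic
    given the data; invariant to row order.
    """
    time = np.asarray(time, float)
    status = np.asarray(status, int)
    x = np.asarray(x, float)
    if status.sum() < min_events:
        raise ValueError(
            f"need at least {min_events} events for stable FP selection "
            f"(got {int(status.sum())})"
        )
    z = (x + pre_shift) / pre_scale
    if np.unique(z).size < 2:
        raise ValueError(f"variable {variable!r} has no variation")
    if np.any(z <= 0):
        raise ValueError(
            f"variable {variable!r} must be strictly positive after "
            "pre-transform for FP modelling"
        )
    if adjusters is not None:
        adjusters = np.atleast_2d(np.asarray(adjusters, float))
        if adjusters.shape[0] != len(time):
            adjusters = adjusters.T

    def fit_powers(powers):
        basis = _fp_basis(z, powers)
        X = basis if adjusters is None else np.column_stack([basis, adjusters])
        try:
            llf, params = _cox_llf(time, status, X)
        except Exception as exc:  # non-convergence: skip candidate
            warnings.warn(f"FP candidate {powers} failed to converge: {exc}")
            return None
        return llf, tuple(params[: len(powers)])

    candidates = fp1_fp2_candidates(power_set)
    fits = {}
    for powers in candidates:
        f = fit_powers(powers)
        if f is not None:
            fits[powers] = f
    if not fits:
        raise RuntimeError(f"no FP candidate converged for {variable!r}")

    fp1_fits = {p: f for p, f in fits.items() if len(p) == 1}
    fp2_fits = {p: f for p, f in fits.items() if len(p) == 2}
    best_fp1 = max(fp1_fits, key=lambda p: fp1_fits[p][0]) if fp1_fits else None
    best_fp2 = max(fp2_fits, key=lambda p: fp2_fits[p][0]) if fp2_fits else None
    llf_null = _null_llf(time, status, adjusters)
    llf_lin = fits[(1.0,)][0] if (1.0,) in fits else None

    dev = lambda llf: -2.0 * llf
    competitor = {
        "null": dev(llf_null),
        "linear": dev(llf_lin) if llf_lin is not None else np.nan,
        "fp1": dev(fp1_fits[best_fp1][0]) if best_fp1 else np.nan,
        "fp2": dev(fp2_fits[best_fp2][0]) if best_fp2 else np.nan,
    }

    def make(powers):
        llf, betas = fits[powers]
        return FPFit(
            variable=variable,
            powers=powers,
            betas=betas,
            pre_shift=pre_shift,
            pre_scale=pre_scale,
            deviance=dev(llf),
            competitor_deviances=competitor,
            closed_test_pvalues=pvals,
        )

    top = best_fp2 if best_fp2 is not None else best_fp1
    llf_top = fits[top][0]
    df_top = 2 * len(top)
    pvals: dict[str, float] = {}
    # stage 1: any effect at all (df = 2 per FP degree of the top model)
    pvals["overall"] = sps.chi2.sf(2.0 * (llf_top - llf_null), df_top)
    if pvals["overall"] > alpha:
        f = make(top)
        return FPFit(
            variable=variable,
            powers=None,
            betas=(),
            pre_shift=pre_shift,
            pre_scale=pre_scale,
            deviance=dev(llf_null),
            competitor_deviances=competitor,
            closed_test_pvalues=pvals,
        )
    # stage 2: does the best FP improve on the straight line
    if llf_lin is not None and len(top) == 2:
        pvals["vs_linear"] = sps.chi2.sf(2.0 * (llf_top - llf_lin), df_top - 1)
        if pvals["vs_linear"] > alpha:
            return make((1.0,))
    elif llf_lin is not None and top != (1.0,):
        pvals["vs_linear"] = sps.chi2.sf(2.0 * (llf_top - llf_lin), df_top - 1)
        if pvals["vs_linear"] > alpha:
            return make((1.0,))
    # stage 3: FP2 against best FP1
    if len(top) == 2 and best_fp1 is not None:
        llf_fp1 = fp1_fits[best_fp1][0]
        pvals["fp2_vs_fp1"] = sps.chi2.sf(2.0 * (llf_top - llf_fp1), 2)
        if pvals["fp2_vs_fp1"] > alpha:
            return make(best_fp1)
    return make(top)


def smooth_baseline(
    step_times,
    step_values,
    power_set: tuple[float, ...] = DEFAULT_POWER_SET,
    alpha: float = 0.05,
    domain: tuple[float, float] = (0.0, 15.0),
) -> FPBaseline:
    """Smooth a step cumulative baseline hazard with an FP function of time.

    Regresses ln(cumulative hazard) on FP bases of (untransformed) time by
    least squares, choosing the best FP2 unless the best FP1 is adequate by
    an F-test at level ``alpha``.  Monotonicity of the smoothed cumulative
    hazard is checked on a 0.1-year grid and flagged — never enforced.
    """
    t = np.asarray(step_times, float)
    v = np.asarray(step_values, float)
    keep = v > 0
    t, v = t[keep], v[keep]
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct event times to smooth a baseline")
    y = np.log(v)

    def ols(powers):
        X = np.column_stack([np.ones_like(t), _fp_basis(t, powers)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return float(resid @ resid), coef

    best = {1: None, 2: None}
    for powers in fp1_fp2_candidates(power_set):
        sse, coef = ols(powers)
        d = len(powers)
        if best[d] is None or sse < best[d][0]:
            best[d] = (sse, coef, powers)
    sse1, coef1, p1 = best[1]
    sse2, coef2, p2 = best[2]
    n = len(t)
    # F-test for the two extra FP2 parameters (power + coefficient)
    df2 = n - 3
    if df2 > 0 and sse2 > 0:
        f = ((sse1 - sse2) / 2.0) / (sse2 / df2)
        p_fp2 = float(sps.f.sf(max(f, 0.0), 2, df2))
    else:
        p_fp2 = 1.0
    if p_fp2 < alpha:
        sse, coef, powers = sse2, coef2, p2
    else:
        sse, coef, powers = sse1, coef1, p1
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    baseline = FPBaseline(
        powers=tuple(powers),
        coefs=tuple(coef[1:]),
        intercept=float(coef[0]),
        domain=domain,
        r_squared=r2,
    )
    grid = np.arange(0.1, domain[1] + 1e-9, 0.1)
    ch = baseline.cumhaz(grid)
    if np.any(np.diff(ch) < 0):
        warnings.warn(
            "smoothed cumulative baseline hazard is non-monotone on the "
            "inspection grid"
        )
        baseline = FPBaseline(
            powers=baseline.powers,
            coefs=baseline.coefs,
            intercept=baseline.intercept,
            domain=baseline.domain,
            r_squared=baseline.r_squared,
            monotone=False,
        )
    return baseline
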