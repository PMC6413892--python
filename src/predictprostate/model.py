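"""Domain types for the competing-risks prostate-cancer prognostic model.

The model combines two cause-specific proportional-hazards models — one for
prostate-cancer-specific mortality (PCSM) and one for non-prostate-cancer
mortality (NPCM) — each consisting of fractional-polynomial (FP) transforms of
continuous covariates, categorical log-hazard coefficients, and a smooth FP
approximation to the log cumulative baseline hazard.  Serialization to/from a
single JSON config is lossless at full float precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np

__all__ = [
    "PatientRecord",
    "FPTerm",
    "CategoricalTerm",
    "FPBaseline",
    "CauseSpecificModel",
    "PredictModel",
    "load_model",
    "save_model",
    "load_default_model",
    "TREATMENT_LEVELS",
    "EVENT_CENSORED",
    "EVENT_PCA_DEATH",
    "EVENT_OTHER_DEATH",
]

TREATMENT_LEVELS = ("conservative", "radical", "hormone")

# event coding in cohort files
EVENT_CENSORED = 0
EVENT_PCA_DEATH = 1
EVENT_OTHER_DEATH = 2

_SCHEMA_VERSION = 1


@dataclass
class PatientRecord:
    """One diagnostic case.

    Covariates are those recorded at diagnosis: age (years), PSA (ng/mL),
    histological grade group (1-5), clinical T-stage (1-4, subcategories
    collapsed), primary treatment, binary comorbidity (Charlson 0 vs 1+,
    ``None`` if unknown) and optional biopsy core counts.  Follow-up
    (``time`` in years, ``event`` coded 0/1/2) is optional — prediction needs
    covariates only.
    """

    id: str
    age: float
    psa: float
    grade_group: int
    t_stage: int
    treatment: str
    comorbidity: int | None = None
    cores_positive: int | None = None
    cores_total: int | None = None
    time: float | None = None
    event: int | None = None

    def ppc_fraction(self) -> float | None:
        """Fraction of biopsy cores positive for cancer, or None if unknown."""
        if self.cores_positive is None or self.cores_total is None:
            return None
        if self.cores_total <= 0:
            return None
        return self.cores_positive / self.cores_total


def _fp_basis(z: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """FP basis functions of a strictly positive argument.

    Power 0 denotes the natural logarithm; a repeated power p contributes
    z**p * ln(z) for its second occurrence (standard FP convention).
    Returns array of shape z.shape + (len(powers),).
    """
    z = np.asarray(z, dtype=float)
    out = np.empty(z.shape + (len(powers),), dtype=float)
    prev: float | None = None
    for j, p in enumerate(powers):
        if prev is not None and p == prev:
            col = out[..., j - 1] * np.log(z)
        elif p == 0:
            col = np.log(z)
        else:
            col = z ** p
        out[..., j] = col
        prev = p
    return out


@dataclass(frozen=True)
class FPTerm:
    """One fractional-polynomial covariate transform with its coefficient(s).

    The covariate x is first mapped through the affine pre-transform
    z = (x + pre_shift) / pre_scale, then through the FP basis of ``powers``,
    and each basis value is centered by subtracting the matching entry of
    ``centers``.  The log-hazard contribution is the dot product with
    ``betas``.
    """

    variable: str
    powers: tuple[float, ...]
    betas: tuple[float, ...]
    pre_shift: float = 0.0
    pre_scale: float = 1.0
    centers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.powers) <= 2:
            raise ValueError("FPTerm supports degree-1 or degree-2 transforms")
        if self.centers is None:
            object.__setattr__(self, "centers", (0.0,) * len(self.powers))
        if len(self.betas) != len(self.powers) or len(self.centers) != len(self.powers):
            raise ValueError("powers, betas and centers must have equal length")

    def _argument(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) + self.pre_shift) / self.pre_scale
        needs_positive = any(p <= 0 for p in self.powers)
        if needs_positive and np.any(z <= 0):
            raise ValueError(
                f"non-positive argument to log/negative power for variable "
                f"{self.variable!r}"
            )
        return z

    def basis(self, x) -> np.ndarray:
        """Centered FP basis values, shape x.shape + (degree,)."""
        z = self._argument(x)
        return _fp_basis(z, self.powers) - np.asarray(self.centers)

    def contribution(self, x) -> np.ndarray:
        """Log-hazard contribution beta . (basis - centers)."""
        return self.basis(x) @ np.asarray(self.betas)


def fp_eval(x, term: FPTerm):
    """Evaluate the centered FP transform of ``term`` at covariate value x.

    For a degree-1 term this is the scalar centered transformed value (the
    quantity multiplied by the term's coefficient in the prognostic index);
    degree-2 terms return the pair of centered basis values.
    """
    b = term.basis(x)
    if len(term.powers) == 1:
        return b[..., 0]
    return b


@dataclass(frozen=True)
class CategoricalTerm:
    """Factor variable with per-level log-hazard coefficients.

    ``betas`` maps level -> beta, with the declared reference level present at
    beta exactly 0.
    """

    variable: str
    reference: str
    betas: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.reference not in self.betas:
            raise ValueError(
                f"reference level {self.reference!r} missing from betas of "
                f"{self.variable!r}"
            )
        if self.betas[self.reference] != 0.0:
            raise ValueError("reference level must have beta exactly 0")
        if not all(math.isfinite(b) for b in self.betas.values()):
            raise ValueError(f"non-finite beta in {self.variable!r}")

    def beta_for(self, level) -> float:
        if isinstance(level, (int, float, np.integer, np.floating)) and not isinstance(
            level, bool
        ):
            key = str(int(level)) if float(level).is_integer() else str(level)
        else:
            key = str(level)
        if key not in self.betas:
            raise KeyError(
                f"unknown level {level!r} for variable {self.variable!r}"
            )
        return self.betas[key]

    def contribution(self, levels) -> np.ndarray:
        return np.asarray([self.beta_for(v) for v in np.atleast_1d(levels)])


@dataclass(frozen=True)
class FPBaseline:
    """Smooth FP approximation to the log cumulative baseline hazard.

    log Lambda0(t) = intercept + sum_j coefs[j] * basis_j(t), valid on
    ``domain`` (years).  ``r_squared`` records the quality of the smoothing
    fit; ``monotone`` is False if the smoothed cumulative hazard decreases
    anywhere on a 0.1-year inspection grid (flagged, never silently fixed).
    """

    powers: tuple[float, ...]
    coefs: tuple[float, ...]
    intercept: float
    domain: tuple[float, float] = (0.0, 15.0)
    r_squared: float | None = None
    monotone: bool = True

    def log_cumhaz(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t <= lo) or np.any(t > hi):
            raise ValueError(f"time outside baseline domain ({lo}, {hi}]")
        return self.intercept + _fp_basis(t, self.powers) @ np.asarray(self.coefs)

    def cumhaz(self, t) -> np.ndarray:
        """Cumulative baseline hazard Lambda0(t)."""
        return np.exp(self.log_cumhaz(t))

    def inverse(self, target) -> np.ndarray:
        """Solve Lambda0(t) = target for t on the domain, vectorized.

        Bracketed bisection to an absolute tolerance below 1e-8 years;
        targets beyond Lambda0(domain_hi) return +inf (no event on the
        domain).  Requires Lambda0 nondecreasing (the shipped baselines are).
        """
        target = np.atleast_1d(np.asarray(target, dtype=float))
        hi = self.domain[1]
        lo = 1e-12
        out = np.full(target.shape, np.inf)
        top = float(self.cumhaz(hi))
        solvable = target <= top
        a = np.full(target.shape, lo)
        b = np.full(target.shape, hi)
        # 64 bisection steps: interval 15 / 2**64 << 1e-8 years
        for _ in range(64):
            mid = 0.5 * (a + b)
            below = self.cumhaz(np.clip(mid, lo, hi)) < target
            a = np.where(below, mid, a)
            b = np.where(below, b, mid)
        out[solvable] = 0.5 * (a + b)[solvable]
        return out


@dataclass(frozen=True)
class CauseSpecificModel:
    """All coefficients and baseline for one cause (PCSM or NPCM)."""

    cause: str
    fp_terms: tuple[FPTerm, ...]
    categorical_terms: tuple[CategoricalTerm, ...]
    baseline: FPBaseline | None = None  # None while coefficients-only (mid-fit)

    def term_for(self, variable: str) -> FPTerm | CategoricalTerm | None:
        for t in self.fp_terms:
            if t.variable == variable:
                return t
        for t in self.categorical_terms:
            if t.variable == variable:
                return t
        return None


@dataclass(frozen=True)
class PredictModel:
    """The complete two-cause model with the optional biopsy-core extension.

    ``ppc_hr`` maps {"lt50", "ge50", "unknown"} to PCSM hazard multipliers for
    percentage-of-positive-cores below/at-or-above 50% or unavailable; the
    unknown multiplier is exactly 1.0 so the base model is recovered when no
    biopsy information exists.
    """

    pcsm: CauseSpecificModel
    npcm: CauseSpecificModel
    ppc_hr: Mapping[str, float] | None = None
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ppc_hr is not None:
            missing = {"lt50", "ge50", "unknown"} - set(self.ppc_hr)
            if missing:
                raise ValueError(f"ppc_hr missing levels: {sorted(missing)}")
            if self.ppc_hr["unknown"] != 1.0:
                raise ValueError("ppc unknown multiplier must be exactly 1.0")

    def cause_model(self, cause: str) -> CauseSpecificModel:
        cause = cause.lower()
        if cause == "pcsm":
            return self.pcsm
        if cause == "npcm":
            return self.npcm
        raise ValueError(f"unknown cause {cause!r} (expected 'pcsm' or 'npcm')")


# ---------------------------------------------------------------------------
# serialization


def _term_to_dict(t: FPTerm) -> dict:
    return {
        "variable": t.variable,
        "powers": list(t.powers),
        "betas": list(t.betas),
        "pre_shift": t.pre_shift,
        "pre_scale": t.pre_scale,
        "centers": list(t.centers),
    }


def _term_from_dict(d: Mapping) -> FPTerm:
    return FPTerm(
        variable=d["variable"],
        powers=tuple(d["powers"]),
        betas=tuple(d["betas"]),
        pre_shift=d.get("pre_shift", 0.0),
        pre_scale=d.get("pre_scale", 1.0),
        centers=tuple(d.get("centers", [0.0] * len(d["powers"]))),
    )


def _cause_to_dict(m: CauseSpecificModel) -> dict:
    return {
        "cause": m.cause,
        "fp_terms": [_term_to_dict(t) for t in m.fp_terms],
        "categorical_terms": [
            {"variable": c.variable, "reference": c.reference, "betas": dict(c.betas)}
            for c in m.categorical_terms
        ],
        "baseline": None
        if m.baseline is None
        else {
            "powers": list(m.baseline.powers),
            "coefs": list(m.baseline.coefs),
            "intercept": m.baseline.intercept,
            "domain": list(m.baseline.domain),
            "r_squared": m.baseline.r_squared,
            "monotone": m.baseline.monotone,
        },
    }


def _cause_from_dict(d: Mapping) -> CauseSpecificModel:
    b = d["baseline"]
    return CauseSpecificModel(
        cause=d["cause"],
        fp_terms=tuple(_term_from_dict(t) for t in d["fp_terms"]),
        categorical_terms=tuple(
            CategoricalTerm(c["variable"], c["reference"], dict(c["betas"]))
            for c in d["categorical_terms"]
        ),
        baseline=None
        if b is None
        else FPBaseline(
            powers=tuple(b["powers"]),
            coefs=tuple(b["coefs"]),
            intercept=b["intercept"],
            domain=tuple(b.get("domain", (0.0, 15.0))),
            r_squared=b.get("r_squared"),
            monotone=b.get("monotone", True),
        ),
    )


def model_to_dict(model: PredictModel) -> dict:
    return {
        "schema_version": _SCHEMA_VERSION,
        "pcsm": _cause_to_dict(model.pcsm),
        "npcm": _cause_to_dict(model.npcm),
        "ppc_hr": dict(model.ppc_hr) if model.ppc_hr is not None else None,
        "metadata": dict(model.metadata),
    }


def model_from_dict(d: Mapping) -> PredictModel:
    version = d.get("schema_version")
    if version != _SCHEMA_VERSION:
        raise ValueError(f"unrecognised model config schema version: {version!r}")
    return PredictModel(
        pcsm=_cause_from_dict(d["pcsm"]),
        npcm=_cause_from_dict(d["npcm"]),
        ppc_hr=d.get("ppc_hr"),
        metadata=d.get("metadata", {}),
    )


def save_model(model: PredictModel, path: str | Path) -> None:
    """Write a model to a JSON config (lossless round trip)."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> PredictModel:
    """Read a model from a JSON config written by :func:`save_model`."""
    return model_from_dict(json.loads(Path(path).read_text()))


def load_default_model() -> PredictModel:
    """The shipped model: published hazard ratios with calibrated baselines."""
    from importlib import resources

    with resources.files("predictprostate").joinpath(
        "data/default_model.json"
    ).open() as fh:
        return model_from_dict(json.load(fh))
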