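"""Structural age models and lognormal variability arithmetic.

This is the mathematical kernel shared by the simulation, regression and
centile modules.  Concentrations are modelled as lognormal around an
age-dependent median ``m(age)``:

    ln C_ij = ln m(age_i) + eta_i + eps_ij,
    eta_i ~ N(0, omega^2),  eps_ij ~ N(0, sigma^2)

where ``eta`` is a subject-level (between-subject) deviation and ``eps``
is residual measurement noise, both on the natural-log scale.  Four
candidate median functions are supported:

    M1 linear       m(a) = b0 * (1 + b1 * a)
    M2 exponential  m(a) = b0 * exp(b1 * a)
    M3 asymptote    m(a) = b_asym + (b0 - b_asym) * exp(-b1 * a)
    M4 logistic     m(a) = b0 + (b_asym - b0) * (L(a) - L(0)) / (1 - L(0)),
                    L(a) = 1 / (1 + exp(-b1 * (a - t50)))

All four satisfy m(0) = b0 exactly ("expected value in infancy").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.stats import norm

__all__ = [
    "MODEL_IDS",
    "StructuralModel",
    "VariabilityModel",
    "AssayLimits",
    "median_at_age",
    "percent_change",
    "iiv_cv_percent",
    "cv_percent_to_omega",
    "below_lloq_probability",
    "model_from_dict",
    "model_to_dict",
]

MODEL_IDS = ("M1_linear", "M2_exponential", "M3_asymptote", "M4_logistic")

#: age range (years) over which a structural model must stay positive
AGE_SUPPORT = (0.0, 13.0)


class InvalidModelError(ValueError):
    """Raised when structural parameters produce a non-positive median."""


@dataclass(frozen=True)
class StructuralModel:
    """One of the four age -> median-concentration functions.

    Parameters
    ----------
    model_id : str
        One of ``MODEL_IDS``.
    beta0 : float
        Median concentration (pg/mL) at age 0 ("expected value in infancy").
    beta1 : float
        Age coefficient per year: slope (M1), log-rate (M2), decay rate
        (M3, must be >= 0), steepness (M4, must be >= 0).
    beta_asym : float, optional
        Asymptotic median concentration (pg/mL); M3 and M4 only.
    t50 : float, optional
        Inflection age in years; M4 only.
    """

    model_id: str
    beta0: float
    beta1: float
    beta_asym: Optional[float] = None
    t50: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise InvalidModelError(f"unknown model_id {self.model_id!r}")
        vals = [self.beta0, self.beta1]
        if self.model_id in ("M3_asymptote", "M4_logistic"):
            if self.beta_asym is None:
                raise InvalidModelError(f"{self.model_id} requires beta_asym")
            vals.append(self.beta_asym)
            if self.beta_asym <= 0:
                raise InvalidModelError("beta_asym must be > 0")
        if self.model_id == "M4_logistic":
            if self.t50 is None:
                raise InvalidModelError("M4_logistic requires t50")
            vals.append(self.t50)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidModelError("non-finite structural parameter")
        if self.beta0 <= 0:
            raise InvalidModelError("beta0 must be > 0")
        if self.model_id == "M1_linear" and 1.0 + self.beta1 * AGE_SUPPORT[1] <= 0:
            raise InvalidModelError(
                f"M1 slope {self.beta1} gives non-positive median on "
                f"[0, {AGE_SUPPORT[1]:g}]"
            )
        if self.model_id in ("M3_asymptote", "M4_logistic") and self.beta1 < 0:
            raise InvalidModelError(f"{self.model_id} requires beta1 >= 0")

    @property
    def n_params(self) -> int:
        """Number of structural parameters."""
        return {"M1_linear": 2, "M2_exponential": 2,
                "M3_asymptote": 3, "M4_logistic": 4}[self.model_id]

    def median(self, age):
        return median_at_age(self, age)


@dataclass(frozen=True)
class VariabilityModel:
    """Between-subject (omega) and residual (sigma) SDs on the log scale."""

    omega: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.omega >= 0.0):
            raise ValueError("omega must be >= 0")
        if not (self.sigma > 0.0):
            raise ValueError("sigma must be > 0")

    @property
    def total_sd(self) -> float:
        return math.hypot(self.omega, self.sigma)


@dataclass(frozen=True)
class AssayLimits:
    """Quantification limits of the immunoassay calibration curve.

    ``lloq``/``uloq`` are the calibration limits in pg/mL; ``dilution``
    scales both for conditions analysed diluted (effective limit =
    calibration limit x dilution factor).
    """

    lloq: float
    uloq: float
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.lloq < self.uloq):
            raise ValueError("need 0 < lloq < uloq")
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")

    @property
    def lloq_effective(self) -> float:
        return self.lloq * self.dilution

    @property
    def uloq_effective(self) -> float:
        return self.uloq * self.dilution


def median_at_age(model: StructuralModel, age):
    """Median concentration m(age) in pg/mL; vectorised over ``age``.

    Raises for negative ages; guaranteed positive on the supported age
    range by the model invariants.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be >= 0")
    mid = model.model_id
    if mid == "M1_linear":
        m = model.beta0 * (1.0 + model.beta1 * a)
    elif mid == "M2_exponential":
        m = model.beta0 * np.exp(model.beta1 * a)
    elif mid == "M3_asymptote":
        m = model.beta_asym + (model.beta0 - model.beta_asym) * np.exp(-model.beta1 * a)
    else:  # M4_logistic, rescaled so m(0) = beta0 exactly
        L = 1.0 / (1.0 + np.exp(-model.beta1 * (a - model.t50)))
        L0 = 1.0 / (1.0 + np.exp(model.beta1 * model.t50))
        if L0 >= 1.0:  # steepness 0 degenerates to a constant
            m = np.full_like(L, model.beta0)
        else:
            m = model.beta0 + (model.beta_asym - model.beta0) * (L - L0) / (1.0 - L0)
    if np.ndim(age) == 0:
        return float(m)
    return m


def percent_change(v0: float, v1: float) -> int:
    """Signed integer percent change from v0 to v1.

    Rounded half away from zero, matching how changes over the age range
    are conventionally tabulated (e.g. (4740, 10859) -> +129).
    """
    if not (v0 > 0):
        raise ValueError("v0 must be > 0")
    x = 100.0 * (v1 / v0 - 1.0)
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def iiv_cv_percent(omega: float) -> float:
    """Exact lognormal coefficient of variation, in percent.

    CV% = 100 * sqrt(exp(omega^2) - 1).  The exact transform is used
    rather than the small-omega approximation 100*omega because
    between-subject CVs here reach several hundred percent.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return 100.0 * math.sqrt(math.expm1(omega ** 2))


def cv_percent_to_omega(cv_percent: float) -> float:
    """Inverse of :func:`iiv_cv_percent`: log-scale SD for a lognormal CV%."""
    if cv_percent < 0:
        raise ValueError("cv_percent must be >= 0")
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


def below_lloq_probability(model: StructuralModel,
                           variability: VariabilityModel,
                           age,
                           limits: AssayLimits):
    """Probability that a measurement at ``age`` falls below the effective LLOQ.

    ln C ~ N(ln m(age), omega^2 + sigma^2), so
    P(C < LLOQ_eff) = Phi((ln LLOQ_eff - ln m(age)) / sqrt(omega^2 + sigma^2)).
    In the degenerate limit omega = sigma = 0 the probability is a step
    function at m(age) = LLOQ_eff.
    """
    m = median_at_age(model, age)
    s = variability.total_sd
    lo = math.log(limits.lloq_effective)
    z = (lo - np.log(m)) / s
    p = norm.cdf(z)
    if np.ndim(age) == 0:
        return float(p)
    return p


def model_to_dict(model: StructuralModel,
                  variability: Optional[VariabilityModel] = None) -> dict:
    """JSON-serialisable descriptor {model_id, beta0, beta1, beta_asym, t50, omega, sigma}."""
    d = {"model_id": model.model_id, "beta0": model.beta0, "beta1": model.beta1,
         "beta_asym": model.beta_asym, "t50": model.t50}
    if variability is not None:
        d["omega"] = variability.omega
        d["sigma"] = variability.sigma
    return d


def model_from_dict(d: dict):
    """Inverse of :func:`model_to_dict`.

    Returns ``StructuralModel`` or ``(StructuralModel, VariabilityModel)``
    when omega/sigma are present.
    """
    model = StructuralModel(model_id=d["model_id"], beta0=d["beta0"],
                            beta1=d["beta1"], beta_asym=d.get("beta_asym"),
                            t50=d.get("t50"))
    if "omega" in d or "sigma" in d:
        return model, VariabilityModel(omega=d["omega"], sigma=d["sigma"])
    return model
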