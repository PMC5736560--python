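"""Univariate censored (Tobit) regression on log concentrations.

Covariate screening for immunoassay data with values below the lower limit
of quantification: observed rows contribute a normal density on the log
scale, left-censored rows contribute the normal CDF at the (log) censoring
bound.  Also provides tie-corrected Kendall correlations and
censoring-aware summary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import AssayLimits
from .simulate import DEFAULT_LIMITS

__all__ = [
    "TobitFit", "fit_tobit", "screen_covariates", "kendall_tau",
    "summarize_concentrations", "COVARIATES",
]

#: supported screening covariates -> (column, unit label, transform)
COVARIATES: Dict[str, Tuple[str, str]] = {
    "age": ("age_years", "per year"),
    "weight_z": ("weight_z", "per SD"),
    "sex": ("sex", "girls vs boys"),
    "vitd": ("vitd_nmol_l", "per 10 nmol/L"),
}


@dataclass(frozen=True)
class TobitFit:
    """Censored linear regression result on the log-concentration scale."""

    covariate: str
    unit: str
    alpha0: float           # intercept, log pg/mL
    alpha1: float           # slope per covariate unit
    sigma_resid: float      # residual SD, log scale
    se_alpha1: float
    p_value: float          # two-sided Wald
    n_obs: int
    n_censored: int
    loglik: float

    @property
    def pct_change_per_unit(self) -> float:
        """100*(exp(alpha1)-1): percent change in concentration per unit."""
        return 100.0 * math.expm1(self.alpha1)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def direction(self) -> str:
        return "increase" if self.alpha1 > 0 else "decrease"


def _tobit_negloglik(theta: np.ndarray, x: np.ndarray, y: np.ndarray,
                     censored: np.ndarray) -> float:
    a0, a1, log_s = theta
    s = math.exp(log_s)
    mu = a0 + a1 * x
    ll = 0.0
    obs = ~censored
    if obs.any():
        r = (y[obs] - mu[obs]) / s
        ll += float(np.sum(-0.5 * r * r - 0.5 * math.log(2 * math.pi) - log_s))
    if censored.any():
        z = (y[censored] - mu[censored]) / s
        ll += float(np.sum(stats.norm.logcdf(z)))
    return -ll


def fit_tobit(y_log: Sequence[float], censored: Sequence[bool],
              x: Sequence[float], covariate: str = "x",
              unit: str = "per unit") -> TobitFit:
    """Maximum-likelihood Tobit fit of log concentration on one covariate.

    Parameters
    ----------
    y_log : log concentrations; for censored rows, the *log censoring
        bound* (log effective LLOQ), not a measurement.
    censored : True where the row is below the LLOQ.
    x : covariate values (already scaled to the reporting unit).

    With no censored rows the estimate coincides with ordinary least
    squares.  Above-ULOQ extrapolated values enter as observed and need no
    special flag here.
    """
    y = np.asarray(y_log, dtype=float)
    c = np.asarray(censored, dtype=bool)
    xv = np.asarray(x, dtype=float)
    if not (len(y) == len(c) == len(xv)):
        raise ValueError("length mismatch")
    if (~c).sum() < 3:
        raise ValueError("need >= 3 non-censored observations")
    if np.ptp(xv) == 0:
        raise ValueError("constant covariate")

    # OLS on uncensored rows as starting point
    obs = ~c
    A = np.column_stack([np.ones(obs.sum()), xv[obs]])
    coef, *_ = np.linalg.lstsq(A, y[obs], rcond=None)
    resid = y[obs] - A @ coef
    s0 = max(float(np.std(resid)), 1e-3)
    theta0 = np.array([coef[0], coef[1], math.log(s0)])

    res = optimize.minimize(_tobit_negloglik, theta0, args=(xv, y, c),
                            method="BFGS", options={"maxiter": 500, "gtol": 1e-8})
    if not np.isfinite(res.fun):
        raise RuntimeError("Tobit likelihood did not converge")
    a0, a1, log_s = res.x

    H = _numeric_hessian(lambda t: _tobit_negloglik(t, xv, y, c), res.x)
    se_a1 = math.nan
    try:
        cov = np.linalg.inv(H)
        if cov[1, 1] > 0:
            se_a1 = math.sqrt(cov[1, 1])
    except np.linalg.LinAlgError:
        pass
    if math.isnan(se_a1):
        p = math.nan
    else:
        p = 2.0 * stats.norm.sf(abs(a1) / se_a1)
    return TobitFit(covariate=covariate, unit=unit, alpha0=float(a0),
                    alpha1=float(a1), sigma_resid=float(math.exp(log_s)),
                    se_alpha1=float(se_a1), p_value=float(p),
                    n_obs=int(len(y)), n_censored=int(c.sum()),
                    loglik=float(-res.fun))


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall rank correlation (tau-b)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv) or len(xv) < 2:
        raise ValueError("need equal-length inputs of length >= 2")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("all-tied input")
    tau = stats.kendalltau(xv, yv).statistic
    return float(tau)


def screen_covariates(observations: pd.DataFrame, subjects: pd.DataFrame,
                      covariates: Iterable[str] = ("age", "weight_z", "sex", "vitd"),
                      limits: Optional[Mapping[str, AssayLimits]] = None,
                      max_censored_fraction: float = 0.5) -> pd.DataFrame:
    """Univariate Tobit screen of each covariate per cytokine x condition.

    Strata with more than ``max_censored_fraction`` of rows below the LLOQ
    are skipped (marked ``skipped=True``): the censored likelihood is too
    weakly identified there to report a slope.  Significance is a two-sided
    Wald p < 0.05 with, deliberately, no multiplicity correction — this is
    a screening analysis.
    """
    covariates = list(covariates)
    unknown = set(covariates) - set(COVARIATES)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}")
    merged = observations.merge(subjects, on="subject_id", validate="m:1")
    rows = []
    for (cytokine, condition), grp in merged.groupby(["cytokine", "condition"],
                                                     sort=True):
        censored = (grp["status"] == "below_lloq").to_numpy()
        frac_censored = censored.mean()
        y_log = np.log(grp["value_pg_ml"].to_numpy(dtype=float))
        for cov in covariates:
            col, unit = COVARIATES[cov]
            base = {"cytokine": cytokine, "condition": condition,
                    "covariate": cov, "unit": unit,
                    "n": len(grp), "n_censored": int(censored.sum()),
                    "frac_censored": float(frac_censored)}
            if frac_censored > max_censored_fraction:
                rows.append({**base, "skipped": True, "pct_change_per_unit": np.nan,
                             "p_value": np.nan, "significant": False,
                             "direction": ""})
                continue
            x = _covariate_values(grp, cov)
            fit = fit_tobit(y_log, censored, x, covariate=cov, unit=unit)
            rows.append({**base, "skipped": False,
                         "pct_change_per_unit": fit.pct_change_per_unit,
                         "p_value": fit.p_value,
                         "significant": bool(fit.significant),
                         "direction": fit.direction})
    return pd.DataFrame(rows)


def _covariate_values(df: pd.DataFrame, cov: str) -> np.ndarray:
    if cov == "sex":
        return (df["sex"] == "girl").to_numpy(dtype=float)
    if cov == "vitd":
        return df["vitd_nmol_l"].to_numpy(dtype=float) / 10.0
    col, _ = COVARIATES[cov]
    return df[col].to_numpy(dtype=float)


def summarize_concentrations(observations: pd.DataFrame,
                             limits: Optional[Mapping[str, AssayLimits]] = None
                             ) -> pd.DataFrame:
    """Censoring-aware summary per cytokine x condition.

    Quantiles treat below-LLOQ rows as tied at the censoring bound; any
    quantile that falls within the censored mass is reported as a
    ``"<bound"`` token rather than a number, and the median is tokenised
    whenever more than half the rows are censored.
    """
    limits = DEFAULT_LIMITS if limits is None else limits
    rows = []
    for (cytokine, condition), grp in observations.groupby(
            ["cytokine", "condition"], sort=True):
        lloq_eff = limits[condition].lloq_effective
        token = f"<{lloq_eff:g}"
        vals = grp["value_pg_ml"].to_numpy(dtype=float)
        status = grp["status"]
        n = len(grp)
        n_below = int((status == "below_lloq").sum())
        n_above = int((status == "above_uloq_extrapolated").sum())
        q = np.percentile(vals, [0, 25, 50, 75, 100])  # type-7 interpolation

        def display(value, is_median=False):
            censored_hit = n_below > 0 and value <= lloq_eff
            if censored_hit or (is_median and n_below > n / 2):
                return token
            return f"{value:g}"

        rows.append({
            "cytokine": cytokine, "condition": condition, "n": n,
            "n_below_lloq": n_below, "pct_below_lloq": round(100.0 * n_below / n),
            "n_above_uloq": n_above, "pct_above_uloq": round(100.0 * n_above / n),
            "median": display(q[2], is_median=True),
            "min": display(q[0]), "max": display(q[4]),
            "p25": display(q[1]), "p75": display(q[3]),
            "median_numeric": q[2], "p25_numeric": q[1], "p75_numeric": q[3],
        })
    return pd.DataFrame(rows)
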