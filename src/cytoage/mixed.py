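"""Censored nonlinear mixed-effects age models, fitted by maximum marginal
likelihood with adaptive Gauss-Hermite quadrature.

The model for subject i, observation j:

    ln C_ij = ln m(age_i; beta) + eta_i + eps_ij
    eta_i ~ N(0, omega^2),   eps_ij ~ N(0, sigma^2)

Observed (and above-ULOQ extrapolated) rows contribute the normal density
of the log value; rows below the limit of quantification contribute the
cumulative probability Phi((ln LLOQ_eff - ln m - eta)/sigma) — the standard
"M3" censoring treatment.  The subject random effect is integrated out
numerically: the integrand is log-concave in eta, so each subject's
posterior mode and curvature are found by Newton iteration and the
quadrature grid is centred and scaled there (adaptive Gauss-Hermite,
21 nodes by default), which is exact whenever the integrand is Gaussian
(all rows uncensored) and highly accurate otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import log_ndtr, logsumexp
from scipy.stats import norm

from .models import (AssayLimits, InvalidModelError, StructuralModel,
                     VariabilityModel, iiv_cv_percent, median_at_age,
                     percent_change)
from .simulate import DEFAULT_LIMITS

__all__ = [
    "GroupedData", "MixedFit", "make_grouped_data", "marginal_loglik",
    "fit_model", "fit_all_models", "select_model", "variance_explained_by_age",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class GroupedData:
    """Observations grouped by subject, ready for the marginal likelihood.

    ``y_log`` holds the log concentration for observed rows and the log
    censoring bound for below-LLOQ rows.
    """

    y_log: np.ndarray
    censored: np.ndarray
    age: np.ndarray
    subject_index: np.ndarray
    n_subjects: int

    def __post_init__(self):
        if len(self.y_log) == 0:
            raise ValueError("empty data")
        if not (len(self.y_log) == len(self.censored) == len(self.age)
                == len(self.subject_index)):
            raise ValueError("length mismatch")

    @property
    def n_obs(self) -> int:
        return len(self.y_log)

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())


def make_grouped_data(observations: pd.DataFrame, subjects: pd.DataFrame,
                      cytokine: Optional[str] = None,
                      condition: Optional[str] = None) -> GroupedData:
    """Build a :class:`GroupedData` for one cytokine x condition stratum."""
    df = observations
    if cytokine is not None:
        df = df[df["cytokine"] == cytokine]
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValueError("no observations for the requested stratum")
    df = df.merge(subjects[["subject_id", "age_years"]], on="subject_id",
                  validate="m:1")
    codes, _ = pd.factorize(df["subject_id"], sort=True)
    return GroupedData(
        y_log=np.log(df["value_pg_ml"].to_numpy(dtype=float)),
        censored=(df["status"] == "below_lloq").to_numpy(),
        age=df["age_years"].to_numpy(dtype=float),
        subject_index=codes.astype(np.intp),
        n_subjects=int(codes.max()) + 1,
    )


def _obs_loglik_terms(r: np.ndarray, censored: np.ndarray, sigma: float,
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-observation log-likelihood, first and second derivatives in eta.

    ``r`` is the residual y_log - ln m(age) - eta.
    """
    ll = np.empty_like(r)
    d1 = np.empty_like(r)
    d2 = np.empty_like(r)
    obs = ~censored
    s2 = sigma * sigma
    ro = r[obs]
    ll[obs] = -0.5 * ro * ro / s2 - math.log(sigma) - 0.5 * _LOG_2PI
    d1[obs] = ro / s2
    d2[obs] = -1.0 / s2
    if censored.any():
        z = r[censored] / sigma
        logcdf = log_ndtr(z)
        ll[censored] = logcdf
        # g = pdf/cdf, the inverse Mills ratio
        g = np.exp(-0.5 * z * z - 0.5 * _LOG_2PI - logcdf)
        d1[censored] = -g / sigma
        d2[censored] = -g * (z + g) / s2
    return ll, d1, d2


def marginal_loglik(model: StructuralModel, variability: VariabilityModel,
                    data: GroupedData, n_nodes: int = 21) -> float:
    """Marginal log-likelihood with the subject effect integrated out.

    sum_i ln Int prod_j l(obs_ij | eta) phi(eta; 0, omega^2) d eta,
    by adaptive Gauss-Hermite quadrature centred at each subject's
    posterior mode.  With omega = 0 the mixture degenerates and the
    likelihood is evaluated at eta = 0.
    """
    omega, sigma = variability.omega, variability.sigma
    m = np.asarray(median_at_age(model, data.age), dtype=float)
    if not np.all(np.isfinite(m)) or np.any(m <= 0):
        raise ValueError("median function non-positive or non-finite")
    base_r = data.y_log - np.log(m)
    idx = data.subject_index

    if omega < 1e-10:
        ll, _, _ = _obs_loglik_terms(base_r, data.censored, sigma)
        return float(ll.sum())

    # Newton iteration for the per-subject posterior mode of eta
    eta = np.zeros(data.n_subjects)
    inv_w2 = 1.0 / (omega * omega)
    for _ in range(60):
        r = base_r - eta[idx]
        _, d1, d2 = _obs_loglik_terms(r, data.censored, sigma)
        grad = eta * inv_w2 - np.bincount(idx, weights=d1, minlength=data.n_subjects)
        hess = inv_w2 - np.bincount(idx, weights=d2, minlength=data.n_subjects)
        step = grad / hess
        # damping keeps the first iterations stable for heavy censoring
        np.clip(step, -4.0 * omega, 4.0 * omega, out=step)
        eta -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    r = base_r - eta[idx]
    _, d1, d2 = _obs_loglik_terms(r, data.censored, sigma)
    hess = inv_w2 - np.bincount(idx, weights=d2, minlength=data.n_subjects)
    scale = 1.0 / np.sqrt(hess)

    x, w = hermgauss(n_nodes)
    log_w = np.log(w)
    # eta grid: (n_subjects, n_nodes)
    eta_grid = eta[:, None] + math.sqrt(2.0) * scale[:, None] * x[None, :]
    r_grid = base_r[:, None] - eta_grid[idx]
    cens = np.broadcast_to(data.censored[:, None], r_grid.shape).ravel()
    ll_flat, _, _ = _obs_loglik_terms(r_grid.ravel(), cens, sigma)
    ll_obs = ll_flat.reshape(r_grid.shape)
    group_ll = np.column_stack([
        np.bincount(idx, weights=ll_obs[:, k], minlength=data.n_subjects)
        for k in range(n_nodes)])
    # -h(eta) = sum_j ll_j(eta) + log phi(eta; 0, omega^2)
    neg_h = (group_ll - 0.5 * eta_grid ** 2 * inv_w2
             - math.log(omega) - 0.5 * _LOG_2PI)
    per_subject = (0.5 * math.log(2.0) + np.log(scale)
                   + logsumexp(log_w[None, :] + x[None, :] ** 2 + neg_h, axis=1))
    return float(per_subject.sum())


# ---------------------------------------------------------------------------
# fitting

#: default residual log-SD used when sigma must be fixed: matches the
#: manufacturer-reported intra/inter-assay repeatability (~20% CV)
ASSAY_SIGMA = 0.2


def _pack_names(model_id: str, fix_beta1: bool, fix_omega: Optional[float],
                fix_sigma: Optional[float]) -> List[str]:
    names = {"M1_linear": ["beta0", "beta1"],
             "M2_exponential": ["beta0", "beta1"],
             "M3_asymptote": ["beta0", "beta1", "beta_asym"],
             "M4_logistic": ["beta0", "beta1", "beta_asym", "t50"]}[model_id]
    if fix_beta1:
        if model_id not in ("M1_linear", "M2_exponential"):
            raise ValueError("fix_beta1 only applies to M1/M2")
        names = ["beta0"]
    if fix_omega is None:
        names = names + ["omega"]
    if fix_sigma is None:
        names = names + ["sigma"]
    return names


def _unpack(u: np.ndarray, model_id: str, fix_beta1: bool,
            fix_omega: Optional[float], fix_sigma: Optional[float],
            ) -> Tuple[StructuralModel, VariabilityModel]:
    i = 0
    beta0 = math.exp(u[i]); i += 1
    if fix_beta1:
        beta1 = 0.0
    elif model_id == "M1_linear":
        # maps R -> (-1/13, inf) so the median stays positive on [0, 13]
        beta1 = (math.exp(u[i]) - 1.0) / 13.0; i += 1
    elif model_id == "M2_exponential":
        beta1 = u[i]; i += 1
    else:
        beta1 = math.exp(u[i]); i += 1
    beta_asym = t50 = None
    if model_id in ("M3_asymptote", "M4_logistic") and not fix_beta1:
        beta_asym = math.exp(u[i]); i += 1
    if model_id == "M4_logistic" and not fix_beta1:
        t50 = u[i]; i += 1
    omega = fix_omega if fix_omega is not None else math.exp(u[i])
    if fix_omega is None:
        i += 1
    sigma = fix_sigma if fix_sigma is not None else math.exp(u[i])
    model = StructuralModel(model_id, beta0, beta1, beta_asym, t50)
    return model, VariabilityModel(omega=omega, sigma=sigma)


def _pack_start(data: GroupedData, model_id: str, fix_beta1: bool,
                fix_omega: Optional[float], fix_sigma: Optional[float]
                ) -> np.ndarray:
    """Data-driven starting point from a naive log-linear regression with
    censored rows substituted at the bound."""
    A = np.column_stack([np.ones(data.n_obs), data.age])
    coef, *_ = np.linalg.lstsq(A, data.y_log, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid_var = float(np.var(data.y_log - A @ coef))
    sigma0 = ASSAY_SIGMA if fix_sigma is None else fix_sigma
    omega0 = math.sqrt(max(resid_var - sigma0 ** 2, 0.04))
    u = [a]
    if not fix_beta1:
        if model_id == "M1_linear":
            b1 = min(max(b, -0.065), 1.0)
            u.append(math.log(1.0 + 13.0 * b1))
        elif model_id == "M2_exponential":
            u.append(b)
        elif model_id == "M3_asymptote":
            u.append(math.log(0.15))
            u.append(a + 12.0 * b)      # log beta_asym from the 12-y end
        else:  # M4
            u.append(math.log(0.5))
            u.append(a + 12.0 * b)
            u.append(6.0)
    if fix_omega is None:
        u.append(math.log(omega0))
    if fix_sigma is None:
        u.append(math.log(ASSAY_SIGMA))
    return np.asarray(u, dtype=float)


@dataclass(frozen=True)
class MixedFit:
    """Result of a censored mixed-effects fit for one stratum."""

    model: StructuralModel
    variability: VariabilityModel
    se: Dict[str, float]
    loglik: float
    n_params: int
    n_subjects: int
    n_obs: int
    n_censored: int
    converged: bool
    se_available: bool
    cytokine: str = ""
    condition: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def value_infancy(self) -> float:
        return median_at_age(self.model, 0.0)

    @property
    def value_12y(self) -> float:
        return median_at_age(self.model, 12.0)

    @property
    def change_12y(self) -> int:
        return percent_change(self.value_infancy, self.value_12y)

    @property
    def iiv_cv(self) -> float:
        return iiv_cv_percent(self.variability.omega)

    @property
    def ruv_cv(self) -> float:
        return iiv_cv_percent(self.variability.sigma)

    def to_dict(self) -> dict:
        return {
            "cytokine": self.cytokine, "condition": self.condition,
            "model_id": self.model.model_id,
            "beta0": self.model.beta0, "beta1": self.model.beta1,
            "beta_asym": self.model.beta_asym, "t50": self.model.t50,
            "omega": self.variability.omega, "sigma": self.variability.sigma,
            "se": self.se, "loglik": self.loglik, "aic": self.aic,
            "n_params": self.n_params, "n_subjects": self.n_subjects,
            "n_obs": self.n_obs, "n_censored": self.n_censored,
            "converged": self.converged, "se_available": self.se_available,
            "value_infancy": self.value_infancy, "value_12y": self.value_12y,
            "change_12y": self.change_12y, "iiv_cv": self.iiv_cv,
            "ruv_cv": self.ruv_cv,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_model(data: GroupedData, model_id: str = "M2_exponential",
              start: Optional[np.ndarray] = None, n_nodes: int = 21,
              n_starts: int = 5, seed: int = 0, fix_beta1: bool = False,
              fix_omega: Optional[float] = None,
              fix_sigma: Optional[float] = "auto",
              cytokine: str = "", condition: str = "") -> MixedFit:
    """Maximum marginal-likelihood fit of one structural model.

    Optimises over (beta, log omega, log sigma) with multi-start (the
    data-driven start plus ``n_starts - 1`` seeded perturbations), keeping
    the best likelihood.  Standard errors come from the finite-difference
    Hessian of the marginal log-likelihood at the optimum; a
    non-positive-definite Hessian flags them unavailable rather than
    failing the fit.  Deterministic given (data, seed, options).

    When every subject contributes a single observation, omega and sigma
    are only jointly identified through the total log-variance; the
    default ``fix_sigma="auto"`` then pins sigma at the assay
    repeatability ``ASSAY_SIGMA`` (0.2, ~20% CV) and estimates omega.
    With replicate observations per subject (e.g. the shared-eta pooled
    mode) both are estimated.  ``fix_omega=0`` collapses the model to a
    fixed-effects nonlinear regression on the log scale.
    """
    if data.n_subjects < 10:
        raise ValueError("need >= 10 subjects")
    if data.n_censored == data.n_obs:
        raise ValueError("all observations censored")
    if fix_sigma == "auto":
        singletons = np.bincount(data.subject_index,
                                 minlength=data.n_subjects).max() <= 1
        fix_sigma = ASSAY_SIGMA if singletons else None

    def nll(u: np.ndarray) -> float:
        try:
            with np.errstate(all="ignore"):
                model, var = _unpack(u, model_id, fix_beta1, fix_omega, fix_sigma)
                val = -marginal_loglik(model, var, data, n_nodes=n_nodes)
        except (InvalidModelError, ValueError, OverflowError, FloatingPointError):
            return 1e10
        return val if np.isfinite(val) else 1e10

    base = (_pack_start(data, model_id, fix_beta1, fix_omega, fix_sigma)
            if start is None else np.asarray(start, float))
    rng = np.random.default_rng(seed)
    starts = [base]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(base + rng.normal(0.0, 0.3, size=base.shape))

    best = None
    for u0 in starts:
        res = optimize.minimize(nll, u0, method="L-BFGS-B",
                                options={"maxiter": 400, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    model, var = _unpack(best.x, model_id, fix_beta1, fix_omega, fix_sigma)
    loglik = -best.fun
    # the optimizer's own status is unreliable with numeric gradients near
    # flat optima; judge convergence by the first-order condition instead
    converged = bool(np.isfinite(loglik) and loglik > -1e9)
    if converged and not best.success:
        h = 1e-5 * np.maximum(np.abs(best.x), 1.0)
        grad = np.array([(nll(best.x + dh) - nll(best.x - dh)) / (2 * h[i])
                         for i, dh in enumerate(np.diag(h))])
        converged = bool(np.max(np.abs(grad)) < 1e-2 * (1.0 + abs(best.fun)))
    names = _pack_names(model_id, fix_beta1, fix_omega, fix_sigma)
    se, se_ok = _standard_errors(nll, best.x, names, model_id, fix_beta1,
                                 fix_omega, fix_sigma)
    return MixedFit(model=model, variability=var, se=se, loglik=loglik,
                    n_params=len(names), n_subjects=data.n_subjects,
                    n_obs=data.n_obs, n_censored=data.n_censored,
                    converged=converged, se_available=se_ok,
                    cytokine=cytokine, condition=condition)


def _standard_errors(nll, u_hat: np.ndarray, names: List[str], model_id: str,
                     fix_beta1: bool, fix_omega: Optional[float],
                     fix_sigma: Optional[float]) -> Tuple[Dict[str, float], bool]:
    """Delta-method SEs on the natural parameter scale from the internal-
    scale Hessian."""
    n = len(u_hat)
    h = 1e-4 * np.maximum(np.abs(u_hat), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            upp = u_hat.copy(); upp[i] += h[i]; upp[j] += h[j]
            upm = u_hat.copy(); upm[i] += h[i]; upm[j] -= h[j]
            ump = u_hat.copy(); ump[i] -= h[i]; ump[j] += h[j]
            umm = u_hat.copy(); umm[i] -= h[i]; umm[j] -= h[j]
            H[i, j] = H[j, i] = ((nll(upp) - nll(upm) - nll(ump) + nll(umm))
                                 / (4 * h[i] * h[j]))
    try:
        cov_u = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {k: math.nan for k in names}, False
    if np.any(np.diag(cov_u) <= 0):
        return {k: math.nan for k in names}, False
    # Jacobian d(natural)/d(internal) is diagonal for every transform used
    model, var = _unpack(u_hat, model_id, fix_beta1, fix_omega, fix_sigma)
    natural = {"beta0": model.beta0, "beta1": model.beta1,
               "beta_asym": model.beta_asym, "t50": model.t50,
               "omega": var.omega, "sigma": var.sigma}
    jac = []
    for i, name in enumerate(names):
        if name == "beta1" and model_id == "M2_exponential":
            jac.append(1.0)
        elif name == "beta1" and model_id == "M1_linear":
            jac.append(math.exp(u_hat[i]) / 13.0)
        elif name == "t50":
            jac.append(1.0)
        else:  # log-transformed positives
            jac.append(abs(natural[name]))
    jac = np.asarray(jac)
    se = np.sqrt(np.diag(cov_u)) * jac
    return {name: float(s) for name, s in zip(names, se)}, True


def fit_all_models(data: GroupedData,
                   model_ids: Sequence[str] = ("M1_linear", "M2_exponential",
                                               "M3_asymptote", "M4_logistic"),
                   **kwargs) -> Dict[str, MixedFit]:
    fits = {}
    for mid in model_ids:
        try:
            fits[mid] = fit_model(data, model_id=mid, **kwargs)
        except (ValueError, RuntimeError):
            continue
    return fits


# tie-break preference among equally-parameterised equivalents: the
# exponential is the conventional reference form for age trends here and
# is kept unless a rival is decisively (>= tie threshold) better
_MODEL_PREFERENCE = {mid: i for i, mid in enumerate(
    ("M2_exponential", "M1_linear", "M3_asymptote", "M4_logistic"))}


def select_model(fits: Mapping[str, MixedFit],
                 aic_tie_threshold: float = 2.0) -> Tuple[str, pd.DataFrame]:
    """AIC ranking with a parsimony tie-break.

    Fits within ``aic_tie_threshold`` of the best AIC are considered
    equivalent; among those the fit with fewest parameters wins, and
    between equally-parameterised equivalents the reference exponential
    form is preferred, then the better AIC.  Returns (chosen model_id,
    ranking table).
    """
    converged = {mid: f for mid, f in fits.items() if f.converged}
    if not converged:
        raise ValueError("no converged fits to select from")
    tab = pd.DataFrame([{"model_id": mid, "n_params": f.n_params,
                         "loglik": f.loglik, "aic": f.aic}
                        for mid, f in converged.items()])
    tab = tab.sort_values("aic", kind="stable").reset_index(drop=True)
    tab["delta_aic"] = tab["aic"] - tab["aic"].iloc[0]
    tied = tab[tab["delta_aic"] < aic_tie_threshold]
    chosen = min(tied.itertuples(),
                 key=lambda r: (r.n_params, _MODEL_PREFERENCE[r.model_id],
                                r.aic)).model_id
    return chosen, tab


def variance_explained_by_age(fit_with_age: MixedFit,
                              fit_no_age: MixedFit) -> float:
    """Percent of between-subject log-variance absorbed by the age model:
    100*(1 - omega_with^2 / omega_without^2), floored at 0."""
    w_with = fit_with_age.variability.omega
    w_without = fit_no_age.variability.omega
    if w_without == 0:
        raise ValueError("reference model has zero between-subject variance")
    return max(0.0, 100.0 * (1.0 - (w_with / w_without) ** 2))
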