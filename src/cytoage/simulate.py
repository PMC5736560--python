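"""Seeded synthetic cohorts of stimulated whole-blood cytokine measurements.

Emulates a paediatric immunoassay study: ~271 children aged 0.1-12.8 years,
eight cytokines (IL-1ra, IL-2, IL-4, IL-6, IL-10, IFN-g, IP-10, TNF-a)
measured unstimulated ("nil") and after in-vitro stimulation with SEB, PHA
and C. albicans.  Concentrations are lognormal around an age-dependent
median with between-subject and residual variability, left-censored at the
assay's lower limit of quantification and extrapolated (kept as observed)
above the upper limit.  SEB/PHA supernatants are analysed at 1:10 dilution,
which scales both limits tenfold.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import fsolve
from scipy.stats import norm

from .models import (AssayLimits, StructuralModel, VariabilityModel,
                     cv_percent_to_omega, median_at_age)

__all__ = [
    "CYTOKINES", "CONDITIONS", "DEFAULT_LIMITS",
    "CohortConfig", "PanelEntry",
    "generate_cohort", "default_panel", "panel_to_yaml", "panel_from_yaml",
    "simulate_concentrations", "apply_quantification_limits",
    "write_subjects_csv", "write_observations_csv",
    "read_subjects_csv", "read_observations_csv",
]

CYTOKINES = ("IL-1ra", "IL-2", "IL-4", "IL-6", "IL-10", "IFN-g", "IP-10", "TNF-a")
CONDITIONS = ("nil", "SEB", "PHA", "C_albicans")

#: calibration range 3.2-10000 pg/mL; SEB/PHA analysed at 1:10 dilution
DEFAULT_LIMITS: Dict[str, AssayLimits] = {
    "nil": AssayLimits(3.2, 10_000.0, 1.0),
    "C_albicans": AssayLimits(3.2, 10_000.0, 1.0),
    "SEB": AssayLimits(3.2, 10_000.0, 10.0),
    "PHA": AssayLimits(3.2, 10_000.0, 10.0),
}

# Reference exponential-model parameterisation of the full panel:
# (condition, cytokine) -> (median in infancy, median at 12 y, IIV CV%).
# A None entry marks a condition where the cytokine sits mostly below the
# LLOQ and no age model is quantifiable; those are simulated from a flat
# sub-LLOQ median (see _UNQUANTIFIABLE below).
_REFERENCE_ROWS: Dict[Tuple[str, str], Optional[Tuple[float, float, float]]] = {
    ("nil", "IL-1ra"): (97.0, 40.0, 244.0),
    ("nil", "IL-2"): None,
    ("nil", "IL-4"): None,
    ("nil", "IL-6"): None,
    ("nil", "IL-10"): None,
    ("nil", "IFN-g"): (5.4, 5.4, 248.0),
    ("nil", "IP-10"): (1071.0, 1071.0, 101.0),
    ("nil", "TNF-a"): (19.5, 7.5, 73.0),
    ("SEB", "IL-1ra"): (1666.0, 801.0, 123.0),
    ("SEB", "IL-2"): (46834.0, 19301.0, 42.0),
    ("SEB", "IL-4"): (458.0, 1614.0, 111.0),
    ("SEB", "IL-6"): (2847.0, 2847.0, 114.0),
    ("SEB", "IL-10"): (2190.0, 4243.0, 76.0),
    ("SEB", "IFN-g"): (19200.0, 38503.0, 104.0),
    ("SEB", "IP-10"): (190133.0, 190133.0, 62.0),
    ("SEB", "TNF-a"): (4740.0, 10859.0, 66.0),
    ("PHA", "IL-1ra"): (505.0, 505.0, 175.0),
    ("PHA", "IL-2"): (225.0, 225.0, 217.0),
    ("PHA", "IL-4"): (358.0, 1829.0, 201.0),
    ("PHA", "IL-6"): (1263.0, 1263.0, 260.0),
    ("PHA", "IL-10"): (146.0, 844.0, 130.0),
    ("PHA", "IFN-g"): (413.0, 1340.0, 135.0),
    ("PHA", "IP-10"): (97973.0, 97973.0, 111.0),
    ("PHA", "TNF-a"): (352.0, 930.0, 157.0),
    ("C_albicans", "IL-1ra"): (372.0, 372.0, 327.0),
    ("C_albicans", "IL-2"): (65.0, 392.0, 641.0),
    ("C_albicans", "IL-4"): (15.0, 49.0, 437.0),
    ("C_albicans", "IL-6"): (22.0, 130.0, 1412.0),
    ("C_albicans", "IL-10"): (15.0, 15.0, 206.0),
    ("C_albicans", "IFN-g"): (22.0, 83.0, 132.0),
    ("C_albicans", "IP-10"): (5601.0, 11235.0, 266.0),
    ("C_albicans", "TNF-a"): (26.0, 57.0, 169.0),
}

# flat median (pg/mL) and IIV CV% for non-quantifiable entries: the
# sub-LLOQ level is set at ~2 pg/mL so the majority of draws censor at 3.2
_UNQUANTIFIABLE = (2.0, 2.0, 120.0)

#: default residual log-SD; corresponds to a residual CV of ~20%
DEFAULT_SIGMA = 0.2


@dataclass(frozen=True)
class PanelEntry:
    """Generative model for one cytokine x stimulation condition."""

    model: StructuralModel
    variability: VariabilityModel
    quantifiable: bool = True


def default_panel(sigma: float = DEFAULT_SIGMA) -> Dict[Tuple[str, str], PanelEntry]:
    """The full 8 cytokine x 4 condition reference panel.

    Quantifiable entries use the exponential age model with the rate
    back-solved from the (infancy, 12-year) median pair; non-quantifiable
    entries use a flat sub-LLOQ median so censoring-heavy strata are
    represented.
    """
    panel: Dict[Tuple[str, str], PanelEntry] = {}
    for (condition, cytokine), row in _REFERENCE_ROWS.items():
        quantifiable = row is not None
        v0, v12, cv = row if quantifiable else _UNQUANTIFIABLE
        beta1 = math.log(v12 / v0) / 12.0
        panel[(cytokine, condition)] = PanelEntry(
            model=StructuralModel("M2_exponential", beta0=v0, beta1=beta1),
            variability=VariabilityModel(omega=cv_percent_to_omega(cv), sigma=sigma),
            quantifiable=quantifiable,
        )
    return panel


def panel_to_yaml(panel: Mapping[Tuple[str, str], PanelEntry], path) -> None:
    rows = []
    for (cytokine, condition), entry in sorted(panel.items()):
        rows.append({
            "cytokine": cytokine, "condition": condition,
            "model_id": entry.model.model_id,
            "beta0": float(entry.model.beta0), "beta1": float(entry.model.beta1),
            "beta_asym": entry.model.beta_asym, "t50": entry.model.t50,
            "omega": float(entry.variability.omega),
            "sigma": float(entry.variability.sigma),
            "quantifiable": bool(entry.quantifiable),
        })
    Path(path).write_text(yaml.safe_dump(rows, sort_keys=False))


def panel_from_yaml(path) -> Dict[Tuple[str, str], PanelEntry]:
    rows = yaml.safe_load(Path(path).read_text())
    panel = {}
    for r in rows:
        model = StructuralModel(r["model_id"], r["beta0"], r["beta1"],
                                r.get("beta_asym"), r.get("t50"))
        var = VariabilityModel(r["omega"], r["sigma"])
        panel[(r["cytokine"], r["condition"])] = PanelEntry(
            model, var, bool(r.get("quantifiable", True)))
    return panel


@dataclass(frozen=True)
class CohortConfig:
    """Distributional targets for the synthetic cohort.

    Ages and vitamin D are truncated lognormal, parameterised by their
    median and inter-quartile range *after* truncation; (age, vitamin D)
    are coupled by a Gaussian copula targeting a negative Kendall tau
    (vitamin D is higher in the youngest children, who are routinely
    supplemented).
    """

    age_median: float = 5.3
    age_iqr: Tuple[float, float] = (3.5, 7.9)
    age_range: Tuple[float, float] = (0.1, 12.8)
    boy_fraction: float = 0.74
    weight_z_mean: float = 0.25
    weight_z_sd: float = 1.11
    vitd_median: float = 54.0
    vitd_iqr: Tuple[float, float] = (40.0, 69.0)
    vitd_range: Tuple[float, float] = (11.0, 142.0)
    kendall_tau_age_vitd: float = -0.13


@lru_cache(maxsize=32)
def _trunc_lognorm_params(q25: float, q50: float, q75: float,
                          lower: float, upper: float) -> Tuple[float, float]:
    """(mu, sdlog) of a lognormal whose [lower, upper]-truncated quartiles
    match the targets (median enters only through the starting point)."""

    def truncated_quantile(mu, sd, p):
        fa = norm.cdf((math.log(lower) - mu) / sd)
        fb = norm.cdf((math.log(upper) - mu) / sd)
        return math.exp(mu + sd * norm.ppf(fa + p * (fb - fa)))

    def equations(theta):
        mu, logsd = theta
        sd = math.exp(logsd)
        return [truncated_quantile(mu, sd, 0.25) - q25,
                truncated_quantile(mu, sd, 0.75) - q75]

    sd0 = (math.log(q75) - math.log(q25)) / (2 * norm.ppf(0.75))
    mu, logsd = fsolve(equations, [math.log(q50), math.log(sd0)], full_output=False)
    return float(mu), float(math.exp(logsd))


def _trunc_lognorm_ppf(u: np.ndarray, mu: float, sd: float,
                       lower: float, upper: float) -> np.ndarray:
    fa = norm.cdf((math.log(lower) - mu) / sd)
    fb = norm.cdf((math.log(upper) - mu) / sd)
    return np.exp(mu + sd * norm.ppf(fa + u * (fb - fa)))


def generate_cohort(n: int, seed: int,
                    config: CohortConfig = CohortConfig()) -> pd.DataFrame:
    """Draw ``n`` synthetic subjects.

    Returns a DataFrame with columns ``subject_id, age_years, sex,
    weight_z, vitd_nmol_l``.  Identical (n, seed, config) yield identical
    output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    mu_a, sd_a = _trunc_lognorm_params(config.age_iqr[0], config.age_median,
                                       config.age_iqr[1], *config.age_range)
    mu_v, sd_v = _trunc_lognorm_params(config.vitd_iqr[0], config.vitd_median,
                                       config.vitd_iqr[1], *config.vitd_range)

    # Gaussian copula: Kendall tau = (2/pi) * arcsin(rho) for the normal pair
    rho = math.sin(math.pi * config.kendall_tau_age_vitd / 2.0)
    z = rng.standard_normal((n, 2))
    z_age = z[:, 0]
    z_vitd = rho * z[:, 0] + math.sqrt(1.0 - rho ** 2) * z[:, 1]
    age = _trunc_lognorm_ppf(norm.cdf(z_age), mu_a, sd_a, *config.age_range)
    vitd = _trunc_lognorm_ppf(norm.cdf(z_vitd), mu_v, sd_v, *config.vitd_range)

    sex = np.where(rng.random(n) < config.boy_fraction, "boy", "girl")
    weight_z = rng.normal(config.weight_z_mean, config.weight_z_sd, n)

    width = max(4, len(str(n)))
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
        "age_years": np.round(age, 4),
        "sex": sex,
        "weight_z": np.round(weight_z, 4),
        "vitd_nmol_l": np.round(vitd, 2),
    })


def simulate_concentrations(subjects: pd.DataFrame,
                            panel: Mapping[Tuple[str, str], PanelEntry],
                            seed: int,
                            shared_eta: bool = False) -> pd.DataFrame:
    """Simulate latent (pre-censoring) concentrations for every subject and
    panel entry.

    true_value_ij = m(age_i) * exp(eta_i) * exp(eps_ij).  By default an
    independent subject deviate eta is drawn per panel entry; with
    ``shared_eta`` one standard-normal deviate per subject x cytokine is
    shared across conditions and scaled by each condition's omega, coupling
    a subject's responses to the different stimulants.
    """
    if subjects.empty:
        raise ValueError("no subjects")
    rng = np.random.default_rng(seed)
    n = len(subjects)
    age = subjects["age_years"].to_numpy(dtype=float)

    shared_z: Dict[str, np.ndarray] = {}
    if shared_eta:
        for cytokine in sorted({k[0] for k in panel}):
            shared_z[cytokine] = rng.standard_normal(n)

    frames = []
    for (cytokine, condition) in sorted(panel.keys()):
        entry = panel[(cytokine, condition)]
        omega, sigma = entry.variability.omega, entry.variability.sigma
        z = shared_z[cytokine] if shared_eta else rng.standard_normal(n)
        eta = omega * z
        eps = sigma * rng.standard_normal(n)
        true_value = median_at_age(entry.model, age) * np.exp(eta + eps)
        frames.append(pd.DataFrame({
            "subject_id": subjects["subject_id"].to_numpy(),
            "cytokine": cytokine,
            "condition": condition,
            "value_pg_ml": true_value,
            "status": "observed",
            "true_value": true_value,
        }))
    return pd.concat(frames, ignore_index=True)


def apply_quantification_limits(observations: pd.DataFrame,
                                limits: Optional[Mapping[str, AssayLimits]] = None
                                ) -> pd.DataFrame:
    """Censor below the effective LLOQ and flag extrapolation above the ULOQ.

    Below-LLOQ values are *replaced by the effective LLOQ* and flagged
    ``below_lloq`` — the stored value is the censoring bound for the
    likelihood, never a measurement.  Above-ULOQ values keep their value
    (extrapolated from the calibration curve) and are flagged
    ``above_uloq_extrapolated``.
    """
    limits = DEFAULT_LIMITS if limits is None else limits
    missing = set(observations["condition"].unique()) - set(limits)
    if missing:
        raise ValueError(f"no assay limits for conditions {sorted(missing)}")
    if (observations["value_pg_ml"] < 0).any():
        raise ValueError("negative concentrations")

    out = observations.copy()
    lloq_eff = out["condition"].map({c: l.lloq_effective for c, l in limits.items()})
    uloq_eff = out["condition"].map({c: l.uloq_effective for c, l in limits.items()})
    below = out["value_pg_ml"] < lloq_eff
    above = out["value_pg_ml"] > uloq_eff
    out["status"] = np.select([below, above], ["below_lloq", "above_uloq_extrapolated"],
                              default="observed")
    out.loc[below, "value_pg_ml"] = lloq_eff[below]
    return out


def write_subjects_csv(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False)


def write_observations_csv(observations: pd.DataFrame, path,
                           include_true_value: bool = False) -> None:
    cols = ["subject_id", "cytokine", "condition", "value_pg_ml", "status"]
    if include_true_value and "true_value" in observations:
        cols.append("true_value")
    observations.to_csv(path, index=False, columns=cols,
                        float_format="%.6g")


def read_subjects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_observations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
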