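"""Age-dependent percentile (reference-range) curves and visual predictive
checks.

A fitted lognormal age model implies closed-form centiles: on the
between-subject basis P_q(age) = m(age) * exp(z_q * omega) describes the
distribution of subjects' underlying levels; the total basis replaces
omega with sqrt(omega^2 + sigma^2) and describes single noisy
measurements.  A Monte-Carlo method simulates individuals per grid age
instead, as a cross-check and for models where no closed form applies.

The visual predictive check (VPC) simulates replicate datasets at the
observed ages — censoring included — and compares observed percentiles per
age bin with the simulation bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import AssayLimits, StructuralModel, VariabilityModel, median_at_age
from .mixed import MixedFit
from .simulate import DEFAULT_LIMITS

__all__ = ["PercentileCurve", "VpcResult", "percentile_curves", "vpc",
           "plot_centiles"]

DEFAULT_AGE_GRID = np.round(np.arange(0.0, 13.0 + 1e-9, 0.1), 1)
DEFAULT_LEVELS = (5.0, 50.0, 95.0)

#: fewest simulated datasets for meaningful VPC bands
MIN_VPC_REPLICATES = 100


@dataclass(frozen=True)
class PercentileCurve:
    """Percentile concentrations on an age grid."""

    age_grid: np.ndarray
    levels: Tuple[float, ...]
    values: np.ndarray          # shape (n_ages, n_levels), pg/mL
    basis: str                  # between_subject | total
    method: str                 # closed_form | monte_carlo
    nsim: Optional[int] = None
    seed: Optional[int] = None

    def to_frame(self, cytokine: str = "", condition: str = "") -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.age_grid):
            for j, lev in enumerate(self.levels):
                rows.append({"age_years": float(a), "level": float(lev),
                             "value_pg_ml": float(self.values[i, j]),
                             "basis": self.basis, "cytokine": cytokine,
                             "condition": condition})
        return pd.DataFrame(rows)


def _model_var(fit_or_model) -> Tuple[StructuralModel, VariabilityModel]:
    if isinstance(fit_or_model, MixedFit):
        if not fit_or_model.converged:
            raise ValueError("cannot derive centiles from a non-converged fit")
        return fit_or_model.model, fit_or_model.variability
    model, var = fit_or_model
    return model, var


def percentile_curves(fit, age_grid: Optional[Sequence[float]] = None,
                      levels: Sequence[float] = DEFAULT_LEVELS,
                      basis: str = "between_subject",
                      method: str = "closed_form",
                      nsim: int = 10_000,
                      seed: Optional[int] = None) -> PercentileCurve:
    """Percentile curves from a fit (or a ``(model, variability)`` pair).

    closed_form: P_q(age) = m(age) * exp(z_q * s) with s = omega
    (between_subject) or sqrt(omega^2 + sigma^2) (total).  monte_carlo:
    empirical percentiles of ``nsim`` simulated individuals per grid age.
    """
    model, var = _model_var(fit)
    if basis not in ("between_subject", "total"):
        raise ValueError(f"unknown basis {basis!r}")
    levels = tuple(float(q) for q in levels)
    if any(not (0.0 < q < 100.0) for q in levels):
        raise ValueError("levels must lie strictly inside (0, 100)")
    ages = DEFAULT_AGE_GRID if age_grid is None else np.asarray(age_grid, float)
    m = np.asarray(median_at_age(model, ages), dtype=float)

    s = var.omega if basis == "between_subject" else var.total_sd
    if method == "closed_form":
        z = norm.ppf(np.asarray(levels) / 100.0)
        values = m[:, None] * np.exp(z[None, :] * s)
        return PercentileCurve(ages, levels, values, basis, method)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        draws = m[:, None] * np.exp(s * rng.standard_normal((len(ages), nsim)))
        values = np.percentile(draws, levels, axis=1).T
        return PercentileCurve(ages, levels, values, basis, method,
                               nsim=nsim, seed=seed)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class VpcResult:
    """Observed vs simulated percentiles per age bin."""

    bin_edges: np.ndarray
    bin_mid_age: np.ndarray
    n_per_bin: np.ndarray
    levels: Tuple[float, ...]
    observed: np.ndarray        # (n_bins, n_levels)
    band_lower: np.ndarray      # (n_bins, n_levels)
    band_upper: np.ndarray
    coverage: np.ndarray        # fraction of bins inside the band, per level
    n_replicates: int
    merged_bins: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(len(self.bin_mid_age)):
            for j, lev in enumerate(self.levels):
                rows.append({
                    "bin_low": float(self.bin_edges[b]),
                    "bin_high": float(self.bin_edges[b + 1]),
                    "bin_mid_age": float(self.bin_mid_age[b]),
                    "n": int(self.n_per_bin[b]), "level": float(lev),
                    "observed": float(self.observed[b, j]),
                    "band_lower": float(self.band_lower[b, j]),
                    "band_upper": float(self.band_upper[b, j]),
                })
        return pd.DataFrame(rows)


def _age_bins(age: np.ndarray, n_bins: int, min_per_bin: int = 3
              ) -> Tuple[np.ndarray, int]:
    """Quantile bin edges over the observed age range; bins with fewer than
    ``min_per_bin`` observations are merged with a neighbour."""
    qs = np.linspace(0.0, 100.0, n_bins + 1)
    edges = np.unique(np.percentile(age, qs))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    merged = 0
    while len(edges) > 2:
        counts, _ = np.histogram(age, edges)
        small = np.flatnonzero(counts < min_per_bin)
        if len(small) == 0:
            break
        i = small[0]
        drop = i + 1 if i + 1 < len(edges) - 1 else i
        edges = np.delete(edges, drop)
        merged += 1
    return edges, merged


def vpc(fit, observations: pd.DataFrame, subjects: pd.DataFrame,
        n_replicates: int = 200, n_bins: int = 6,
        seed: Optional[int] = None,
        levels: Sequence[float] = DEFAULT_LEVELS,
        limits: Optional[Mapping[str, AssayLimits]] = None,
        band: float = 90.0) -> VpcResult:
    """Visual predictive check of a fit against the observed stratum.

    Simulates ``n_replicates`` datasets at the observed ages under the
    fitted model, applies the quantification limits of the stratum's
    condition (censored rows are placed at the bound, mirroring the
    observed data handling), and summarises the 5th/50th/95th percentile
    per age bin of every replicate.  The band is the central ``band``%
    interval of each percentile across replicates.
    """
    model, var = _model_var(fit)
    if n_replicates < MIN_VPC_REPLICATES:
        raise ValueError(f"n_replicates must be >= {MIN_VPC_REPLICATES}")
    levels = tuple(float(q) for q in levels)
    limits = DEFAULT_LIMITS if limits is None else limits

    conditions = observations["condition"].unique()
    cytokines = observations["cytokine"].unique()
    if len(conditions) != 1 or len(cytokines) != 1:
        raise ValueError("vpc expects observations from a single "
                         "cytokine x condition stratum")
    lim = limits[conditions[0]]

    df = observations.merge(subjects[["subject_id", "age_years"]],
                            on="subject_id", validate="m:1")
    age = df["age_years"].to_numpy(dtype=float)
    obs_values = df["value_pg_ml"].to_numpy(dtype=float)
    n = len(df)

    edges, merged = _age_bins(age, n_bins)
    bin_idx = np.digitize(age, edges) - 1
    n_bins_eff = len(edges) - 1
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.bincount(bin_idx, minlength=n_bins_eff)

    def bin_percentiles(values: np.ndarray) -> np.ndarray:
        out = np.empty((n_bins_eff, len(levels)))
        for b in range(n_bins_eff):
            out[b] = np.percentile(values[bin_idx == b], levels)
        return out

    observed_pct = bin_percentiles(obs_values)

    rng = np.random.default_rng(seed)
    m = median_at_age(model, age)
    sim_pct = np.empty((n_replicates, n_bins_eff, len(levels)))
    for r in range(n_replicates):
        eta = var.omega * rng.standard_normal(n)
        eps = var.sigma * rng.standard_normal(n)
        sim = m * np.exp(eta + eps)
        sim = np.where(sim < lim.lloq_effective, lim.lloq_effective, sim)
        sim_pct[r] = bin_percentiles(sim)

    lo = (100.0 - band) / 2.0
    band_lower = np.percentile(sim_pct, lo, axis=0)
    band_upper = np.percentile(sim_pct, 100.0 - lo, axis=0)
    inside = (observed_pct >= band_lower) & (observed_pct <= band_upper)
    coverage = inside.mean(axis=0)
    return VpcResult(bin_edges=edges, bin_mid_age=mids, n_per_bin=counts,
                     levels=levels, observed=observed_pct,
                     band_lower=band_lower, band_upper=band_upper,
                     coverage=coverage, n_replicates=n_replicates,
                     merged_bins=merged)


def plot_centiles(curve: PercentileCurve, path, cytokine: str = "",
                  condition: str = "",
                  observations: Optional[pd.DataFrame] = None,
                  subjects: Optional[pd.DataFrame] = None) -> None:
    """Semi-log centile plot (log10 concentration vs age), optionally with
    the observed points overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if observations is not None and subjects is not None:
        df = observations.merge(subjects[["subject_id", "age_years"]],
                                on="subject_id")
        ax.plot(df["age_years"], df["value_pg_ml"], "o", ms=3, alpha=0.3,
                color="grey")
    for j, lev in enumerate(curve.levels):
        style = "-" if abs(lev - 50.0) < 1e-9 else ":"
        ax.plot(curve.age_grid, curve.values[:, j], style, color="black",
                label=f"P{lev:g}")
    ax.set_yscale("log")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("concentration (pg/mL)")
    title = " / ".join(s for s in (cytokine, condition) if s)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
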