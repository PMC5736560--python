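"""Censored nonlinear mixed-effects estimation and model selection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import curve_fit

from cytoage.mixed import (GroupedData, fit_all_models, fit_model,
                           make_grouped_data, marginal_loglik, select_model,
                           variance_explained_by_age)
from cytoage.models import StructuralModel, VariabilityModel
from cytoage.simulate import (PanelEntry, apply_quantification_limits,
                              generate_cohort, simulate_concentrations)

from conftest import SEB_TNFA, seb_tnfa_panel


def _m2(beta0=100.0, beta1=0.05):
    return StructuralModel("M2_exponential", beta0, beta1)


def _grouped(y_log, censored, age, subject_index):
    subject_index = np.asarray(subject_index, dtype=np.intp)
    return GroupedData(np.asarray(y_log, float), np.asarray(censored, bool),
                       np.asarray(age, float), subject_index,
                       int(subject_index.max()) + 1)


class TestMarginalLoglik:
    def test_degenerate_uncensored_closed_form(self):
        data = _grouped([math.log(120.0)], [False], [3.0], [0])
        model, var = _m2(), VariabilityModel(0.0, 0.3)
        expected = stats.norm.logpdf(math.log(120.0),
                                     math.log(100.0) + 0.05 * 3.0, 0.3)
        assert marginal_loglik(model, var, data) == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_degenerate_censored_at_median_is_log_half(self):
        model = _m2(beta0=3.2, beta1=0.0)
        data = _grouped([math.log(3.2)], [True], [5.0], [0])
        ll = marginal_loglik(model, VariabilityModel(0.0, 0.2), data)
        assert ll == pytest.approx(math.log(0.5), rel=1e-12)

    def test_matches_trapezoid_oracle(self):
        """3 subjects x 2 observations vs 2001-point trapezoid over eta."""
        model, var = _m2(80.0, 0.08), VariabilityModel(0.5, 0.25)
        rng = np.random.default_rng(3)
        age = np.repeat([1.0, 4.0, 9.0], 2)
        idx = np.repeat([0, 1, 2], 2)
        eta = var.omega * rng.standard_normal(3)
        y = (np.log(80.0) + 0.08 * age + eta[idx]
             + var.sigma * rng.standard_normal(6))
        censored = np.array([False, True, False, False, True, False])
        data = _grouped(y, censored, age, idx)

        total = 0.0
        grid = np.linspace(-6 * var.omega, 6 * var.omega, 2001)
        for i in range(3):
            sel = data.subject_index == i
            like = np.ones_like(grid)
            for yj, cj, aj in zip(data.y_log[sel], data.censored[sel],
                                  data.age[sel]):
                mu = math.log(80.0) + 0.08 * aj
                if cj:
                    like *= stats.norm.cdf((yj - mu - grid) / var.sigma)
                else:
                    like *= stats.norm.pdf(yj - mu - grid, 0, var.sigma)
            density = stats.norm.pdf(grid, 0, var.omega)
            total += math.log(np.trapezoid(like * density, grid))
        ll = marginal_loglik(model, var, data)
        assert ll == pytest.approx(total, rel=1e-6)

    def test_invariant_under_reordering(self):
        model, var = _m2(), VariabilityModel(0.4, 0.2)
        rng = np.random.default_rng(5)
        age = rng.uniform(0.5, 12, 12)
        idx = np.repeat(np.arange(4), 3)
        y = np.log(100.0) + 0.05 * age + rng.normal(0, 0.4, 12)
        cens = rng.random(12) < 0.2
        data = _grouped(y, cens, age, idx)
        perm = rng.permutation(12)
        relabel = {0: 2, 1: 0, 2: 3, 3: 1}
        data_perm = _grouped(y[perm], cens[perm], age[perm],
                             [relabel[i] for i in idx[perm]])
        assert marginal_loglik(model, var, data) == pytest.approx(
            marginal_loglik(model, var, data_perm), rel=1e-12)

    def test_quadrature_converged_at_default_nodes(self, cohort,
                                                   seb_tnfa_observations):
        data = make_grouped_data(seb_tnfa_observations, cohort)
        model = StructuralModel("M2_exponential", SEB_TNFA["beta0"],
                                SEB_TNFA["beta1"])
        var = VariabilityModel(SEB_TNFA["omega"], SEB_TNFA["sigma"])
        ll21 = marginal_loglik(model, var, data, n_nodes=21)
        ll41 = marginal_loglik(model, var, data, n_nodes=41)
        assert abs(ll21 - ll41) < 1e-4


class TestFitModel:
    def test_near_noise_free_recovery(self):
        subj = generate_cohort(100, seed=40)
        entry = PanelEntry(_m2(250.0, 0.09), VariabilityModel(0.0, 0.01))
        obs = simulate_concentrations(subj, {("IFN-g", "PHA"): entry}, seed=41)
        data = make_grouped_data(obs, subj)
        fit = fit_model(data, "M2_exponential", fix_omega=0.0,
                        fix_sigma=None, n_starts=2)
        assert fit.model.beta0 == pytest.approx(250.0, rel=0.01)
        assert fit.model.beta1 == pytest.approx(0.09, rel=0.01)

    def test_uncensored_fixed_effects_equals_log_scale_nls(self):
        subj = generate_cohort(80, seed=42)
        entry = PanelEntry(_m2(300.0, 0.07), VariabilityModel(0.0, 0.3))
        obs = simulate_concentrations(subj, {("IL-10", "PHA"): entry}, seed=43)
        data = make_grouped_data(obs, subj)
        fit = fit_model(data, "M2_exponential", fix_omega=0.0, fix_sigma=None,
                        n_starts=2)
        popt, _ = curve_fit(lambda a, lb0, b1: lb0 + b1 * a, data.age,
                            data.y_log, p0=[5.0, 0.05])
        assert math.log(fit.model.beta0) == pytest.approx(popt[0], abs=1e-4)
        assert fit.model.beta1 == pytest.approx(popt[1], abs=1e-4)

    def test_deterministic_refit(self, cohort, seb_tnfa_observations):
        data = make_grouped_data(seb_tnfa_observations, cohort)
        f1 = fit_model(data, "M2_exponential", seed=3, n_starts=3)
        f2 = fit_model(data, "M2_exponential", seed=3, n_starts=3)
        assert f1.model == f2.model
        assert f1.loglik == f2.loglik

    def test_aic_identity_and_derived_quantities(self, cohort,
                                                 seb_tnfa_observations):
        data = make_grouped_data(seb_tnfa_observations, cohort)
        fit = fit_model(data, "M2_exponential", seed=0, n_starts=2)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        assert fit.value_infancy == pytest.approx(fit.model.beta0)
        from cytoage.models import percent_change
        assert fit.change_12y == percent_change(fit.value_infancy, fit.value_12y)
        assert fit.converged and fit.se_available
        assert fit.se["beta0"] > 0

    def test_error_cases(self, cohort, seb_tnfa_observations):
        data = make_grouped_data(seb_tnfa_observations, cohort)
        small = GroupedData(data.y_log[:5], data.censored[:5], data.age[:5],
                            np.arange(5, dtype=np.intp), 5)
        with pytest.raises(ValueError):
            fit_model(small)
        all_cens = GroupedData(data.y_log, np.ones(data.n_obs, bool),
                               data.age, data.subject_index, data.n_subjects)
        with pytest.raises(ValueError):
            fit_model(all_cens)

    def test_asymptote_nests_decreasing_exponential(self, cohort):
        """For a decaying stratum the asymptote model attains at least the
        exponential model's likelihood (its beta_asym -> 0 boundary)."""
        entry = PanelEntry(StructuralModel("M2_exponential", 19.5,
                                           math.log(7.5 / 19.5) / 12.0),
                           VariabilityModel(0.55, 0.2))
        obs = apply_quantification_limits(
            simulate_concentrations(cohort, {("TNF-a", "nil"): entry}, seed=44))
        data = make_grouped_data(obs, cohort)
        f2 = fit_model(data, "M2_exponential", seed=1, n_starts=3)
        f3 = fit_model(data, "M3_asymptote", seed=1, n_starts=3)
        assert f3.loglik >= f2.loglik - 0.05


class TestModelSelection:
    def test_single_fit_returned_trivially(self, cohort, seb_tnfa_observations):
        data = make_grouped_data(seb_tnfa_observations, cohort)
        fit = fit_model(data, "M2_exponential", seed=0, n_starts=1)
        chosen, tab = select_model({"M2_exponential": fit})
        assert chosen == "M2_exponential"
        assert len(tab) == 1 and tab.loc[0, "delta_aic"] == 0.0

    def test_parsimony_tie_break_prefers_fewer_parameters(self):
        from cytoage.mixed import MixedFit

        def fake(n_params, loglik):
            return MixedFit(model=_m2(), variability=VariabilityModel(0.3, 0.2),
                            se={}, loglik=loglik, n_params=n_params,
                            n_subjects=100, n_obs=100, n_censored=0,
                            converged=True, se_available=True)
        fits = {"M2_exponential": fake(3, -100.0),
                "M3_asymptote": fake(4, -99.5)}
        chosen, _ = select_model(fits)
        assert chosen == "M2_exponential"  # dAIC = 1 < 2, fewer params win
        fits["M3_asymptote"] = fake(4, -97.0)
        chosen, _ = select_model(fits)
        assert chosen == "M3_asymptote"    # decisively better now

    def test_no_converged_fits_raises(self):
        from cytoage.mixed import MixedFit
        bad = MixedFit(model=_m2(), variability=VariabilityModel(0.3, 0.2),
                       se={}, loglik=-1e10, n_params=3, n_subjects=10,
                       n_obs=10, n_censored=0, converged=False,
                       se_available=False)
        with pytest.raises(ValueError):
            select_model({"M2_exponential": bad})


class TestVarianceExplained:
    def _fit_like(self, omega):
        from cytoage.mixed import MixedFit
        return MixedFit(model=_m2(), variability=VariabilityModel(omega, 0.2),
                        se={}, loglik=-100.0, n_params=3, n_subjects=100,
                        n_obs=100, n_censored=0, converged=True,
                        se_available=True)

    def test_identical_omegas_give_zero(self):
        assert variance_explained_by_age(self._fit_like(0.5),
                                         self._fit_like(0.5)) == 0.0

    def test_floor_at_zero(self):
        assert variance_explained_by_age(self._fit_like(0.6),
                                         self._fit_like(0.5)) == 0.0

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            variance_explained_by_age(self._fit_like(0.3), self._fit_like(0.0))

    def test_recovers_constructed_share(self):
        """Age absorbs a designed share of the log-variance."""
        subj = generate_cohort(271, seed=50)
        entry = PanelEntry(_m2(100.0, 0.10), VariabilityModel(0.45, 0.2))
        obs = simulate_concentrations(subj, {("IL-4", "SEB"): entry}, seed=51)
        data = make_grouped_data(obs, subj)
        f_age = fit_model(data, "M2_exponential", seed=0, n_starts=2)
        f_null = fit_model(data, "M2_exponential", seed=0, n_starts=2,
                           fix_beta1=True)
        got = variance_explained_by_age(f_age, f_null)
        # designed share: var(beta1*age) / (var(beta1*age) + omega^2)
        age_var = float(np.var(subj["age_years"])) * 0.10 ** 2
        expected = 100.0 * age_var / (age_var + 0.45 ** 2)
        assert got == pytest.approx(expected, abs=10.0)
        assert f_null.n_params == f_age.n_params - 1
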