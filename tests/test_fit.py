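"""Optimization, standard errors, and the standardized solution."""

import numpy as np
import pandas as pd
import pytest

from latentchange.builders import (
    MeasurementSchema,
    build_longitudinal_cfa,
    build_univariate_lcsm,
    saturated_spec,
)
from latentchange.fit import FitOptions, fit_model
from latentchange.model import ModelSpec, ParamMatrices

from conftest import make_exact_moments_data


class TestOptimization:
    def test_saturated_fit_reproduces_sample_moments(self, fast_options):
        mu = np.array([1.0, -2.0, 0.5])
        sigma = np.array([[2.0, 0.5, 0.2], [0.5, 1.5, 0.3], [0.2, 0.3, 1.0]])
        data = make_exact_moments_data(mu, sigma, 200)
        fit = fit_model(saturated_spec(list(data.columns)), data, fast_options)
        assert fit.converged
        for i, name in enumerate(data.columns):
            assert fit.estimates[f"mu_{name}"] == pytest.approx(mu[i], abs=1e-5)
            assert fit.estimates[f"s_{name}_{name}"] == pytest.approx(sigma[i, i], abs=1e-5)
        assert fit.estimates["s_y1_y0"] == pytest.approx(0.5, abs=1e-5)

    def test_one_factor_triad_closed_form(self, fast_options):
        # sample cov [[2,1,1],[1,2,1],[1,1,2]] with marker lam1=1 has the
        # closed-form solution psi=1, lam2=lam3=1, all theta=1
        sigma = np.array([[2.0, 1, 1], [1, 2.0, 1], [1, 1, 2.0]])
        data = make_exact_moments_data(np.zeros(3), sigma, 300)
        m = ParamMatrices(3, 1)
        m.set_fixed("lam", (0, 0), 1.0)
        m.set_free("lam", (1, 0), "l2", 1.0)
        m.set_free("lam", (2, 0), "l3", 1.0)
        m.set_free("psi", (0, 0), "psi", 1.0)
        for i in range(3):
            m.set_free("theta", (i, i), f"th{i}", 1.0)
        m.set_free("nu", (1,), "nu1", 0.0)
        m.set_free("nu", (2,), "nu2", 0.0)
        m.set_free("alpha", (0,), "a", 0.0)
        spec = ModelSpec(list(data.columns), ["f"], [m])
        fit = fit_model(spec, data, fast_options)
        assert fit.converged
        for lab in ("l2", "l3", "psi", "th0", "th1", "th2"):
            assert fit.estimates[lab] == pytest.approx(1.0, abs=1e-5)

    def test_heywood_case_flagged_not_raised(self, fast_options):
        # s12*s13/s23 = .75*.70/.40 = 1.31 > s11 forces a negative residual
        sigma = np.array([[1.0, 0.75, 0.70], [0.75, 1.0, 0.40], [0.70, 0.40, 1.0]])
        data = make_exact_moments_data(np.zeros(3), sigma, 300)
        m = ParamMatrices(3, 1)
        m.set_fixed("lam", (0, 0), 1.0)
        m.set_free("lam", (1, 0), "l2", 1.0)
        m.set_free("lam", (2, 0), "l3", 1.0)
        m.set_free("psi", (0, 0), "psi", 1.0)
        for i in range(3):
            m.set_free("theta", (i, i), f"th{i}", 1.0)
        m.set_free("nu", (1,), "nu1", 0.0)
        m.set_free("nu", (2,), "nu2", 0.0)
        m.set_free("alpha", (0,), "a", 0.0)
        fit = fit_model(ModelSpec(list(data.columns), ["f"], [m]), data, fast_options)
        assert fit.converged
        assert fit.estimates["th0"] < 0
        assert any("Heywood" in w for w in fit.warnings)

    def test_non_convergence_flagged_not_raised(self, cohort, schema):
        opts = FitOptions(se="none", compute_baselines=False, max_iter=2,
                          restarts=0, newton_steps=0)
        fit = fit_model(build_longitudinal_cfa(schema, "strong"), cohort, opts)
        assert not fit.converged
        assert any("non-convergence" in w for w in fit.warnings)

    def test_weak_constraint_makes_wave_loadings_bit_identical(self, cohort, schema):
        fit = fit_model(build_longitudinal_cfa(schema, "weak"), cohort,
                        FitOptions(se="none", compute_baselines=False))
        assert fit.converged
        mats = fit.spec.matrices[0].copy()
        mats.set_values(fit.estimates)
        lam = mats.values["lam"]
        n_ind = len(schema.indicators)
        for i in range(n_ind):
            assert lam[i, 0] == lam[n_ind + i, 1]  # bit-exact shared label


class TestStandardErrors:
    def test_saturated_mean_se_closed_form(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame({"y": rng.standard_normal(400) * 2.0 + 1.0})
        fit = fit_model(saturated_spec(["y"]), x,
                        FitOptions(se="observed_information", compute_baselines=False))
        s2 = x["y"].var(ddof=0)
        assert fit.se["mu_y"] == pytest.approx(np.sqrt(s2 / len(x)), rel=1e-3)

    def test_sandwich_close_to_observed_information_under_normality(self, fast_options):
        rng = np.random.default_rng(13)
        n = 4000
        x1 = rng.normal(50, 7, n)
        y1 = rng.normal(50, 7, n)
        x2 = x1 + rng.normal(0, 3, n) - 0.3 * x1 + 10
        y2 = y1 + rng.normal(0, 3, n) - 0.3 * y1 + 10
        data = pd.DataFrame({"x_t1": x1, "x_t2": x2, "y_t1": y1, "y_t2": y2})
        spec = build_univariate_lcsm("x", "y")
        fit_o = fit_model(spec, data, FitOptions(se="observed_information",
                                                 compute_baselines=False))
        fit_s = fit_model(spec, data, FitOptions(se="sandwich", compute_baselines=False))
        for lab in fit_o.labels:
            assert fit_s.se[lab] == pytest.approx(fit_o.se[lab], rel=0.12), lab

    def test_robust_se_of_pse_self_feedback_scales_to_reported_order(self, lcsm_fit):
        # published order: SE ~ .02 at n ~ 9,500; at n = 2,000 expect ~ .02 sqrt(9500/2000)
        se = lcsm_fit.se["self_feedback_pse"]
        assert 0.02 < se < 0.07


class TestStandardizedSolution:
    def test_covariance_standardizes_to_correlation(self, fast_options):
        # cov 2 between variables of variances 4 and 25 -> .2
        sigma = np.array([[4.0, 2.0], [2.0, 25.0]])
        data = make_exact_moments_data(np.zeros(2), sigma, 150)
        m = ParamMatrices(2, 2)
        m.set_fixed("lam", (0, 0), 1.0)
        m.set_fixed("lam", (1, 1), 1.0)
        m.set_free("psi", (0, 0), "v1", 1.0)
        m.set_free("psi", (1, 1), "v2", 1.0)
        m.set_free("psi", (1, 0), "c", 0.0)
        m.set_free("alpha", (0,), "a1", 0.0)
        m.set_free("alpha", (1,), "a2", 0.0)
        fit = fit_model(ModelSpec(list(data.columns), ["f1", "f2"], [m]), data, fast_options)
        assert fit.std_all["c"] == pytest.approx(0.2, abs=1e-4)
        # exogenous variance proportions are exactly 1 by construction
        assert fit.std_all["v1"] == pytest.approx(1.0, abs=1e-6)

    def test_change_variance_ratio_contract(self, lcsm_fit):
        # standardized change variance = estimate / implied total variance,
        # where the total follows from the structural algebra
        e = lcsm_fit.estimates
        total = (
            e["self_feedback_ct"] ** 2 * e["var_ct_t1"]
            + e["coupling_pse_ct"] ** 2 * e["var_pse_t1"]
            + 2 * e["self_feedback_ct"] * e["coupling_pse_ct"] * e["baseline_covariance"]
            + e["var_delta_ct"]
        )
        assert lcsm_fit.std_all["var_delta_ct"] == pytest.approx(
            e["var_delta_ct"] / total, rel=1e-6
        )

    def test_standardized_covariances_bounded(self, lcsm_fit):
        for lab in ("change_covariance", "baseline_covariance"):
            assert -1.0 <= lcsm_fit.std_all[lab] <= 1.0
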