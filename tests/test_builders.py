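"""Builder outputs: free-parameter enumeration, fixed paths, multi-group expansion."""

import numpy as np
import pytest

from latentchange.builders import (
    MeasurementSchema,
    build_bivariate_lcsm,
    build_longitudinal_cfa,
    build_univariate_lcsm,
    expand_multigroup,
)
from latentchange.fit import FitOptions, fit_model
from latentchange.model import ModelError, implied_moments
from latentchange.simulate import canonical_params, params_to_values

from conftest import make_exact_moments_data


class TestFreeCellEnumeration:
    @pytest.mark.parametrize(
        "level,q,df",
        [("configural", 50, 69), ("weak", 44, 75), ("strong", 38, 81), ("partial", 40, 79)],
    )
    def test_longitudinal_cfa_counts(self, schema, level, q, df):
        spec = build_longitudinal_cfa(schema, level)
        assert spec.n_free == q
        assert spec.df == df

    def test_partial_count_tracks_freed_intercepts(self):
        schema = MeasurementSchema(freed_intercepts=("family_coh",))
        assert build_longitudinal_cfa(schema, "partial").n_free == 39

    def test_bivariate_lcsm_strong_counts(self, schema):
        spec = build_bivariate_lcsm(schema)
        assert spec.n_free == 46
        assert spec.n_moments == 16 * 19 // 2
        assert spec.df == 106

    def test_univariate_lcsm_counts(self):
        assert build_univariate_lcsm("x", "y").df == 1
        assert build_univariate_lcsm("x", "y").n_free == 13
        reduced = build_univariate_lcsm("x", "y", coupling=False, change_covariance=False)
        assert reduced.df == 3

    def test_single_indicator_configural_is_underidentified(self):
        schema = MeasurementSchema(indicators=("school_env",), marker="school_env",
                                   freed_intercepts=())
        with pytest.raises(ModelError, match="not identified"):
            build_longitudinal_cfa(schema, "configural")

    def test_unknown_level_rejected(self, schema):
        with pytest.raises(ModelError, match="unknown invariance level"):
            build_longitudinal_cfa(schema, "strict")


class TestLcsmStructure:
    def test_change_score_identity_paths_fixed_at_unit(self, schema):
        mats = build_bivariate_lcsm(schema).matrices[0]
        lat = build_bivariate_lcsm(schema).latent_names
        beta, labels = mats.values["beta"], mats.labels["beta"]
        for head, tail in (("pse_t2", "pse_t1"), ("pse_t2", "delta_pse"),
                           ("ct_t2", "ct_t1"), ("ct_t2", "delta_ct")):
            i, j = lat.index(head), lat.index(tail)
            assert beta[i, j] == 1.0 and labels[i, j] is None
        # wave-2 residual variances fixed at zero
        psi = mats.values["psi"]
        for name in ("pse_t2", "ct_t2"):
            k = lat.index(name)
            assert psi[k, k] == 0.0 and mats.labels["psi"][k, k] is None

    def test_structural_labels_cover_reported_parameter_rows(self, schema):
        labels = set(build_bivariate_lcsm(schema).free_labels())
        for lab in ("change_covariance", "coupling_pse_ct", "self_feedback_pse",
                    "self_feedback_ct", "baseline_covariance", "intercept_delta_pse",
                    "intercept_delta_ct", "var_delta_pse", "var_delta_ct"):
            assert lab in labels

    def test_null_structural_values_degenerate_to_no_change(self, schema):
        # beta = gamma = phi = 0 with zero change variance and intercepts
        # implies identical wave-1 and wave-2 moments
        params = canonical_params()
        values = params_to_values(params)
        for lab in ("self_feedback_pse", "self_feedback_ct", "coupling_pse_ct",
                    "change_covariance", "var_delta_pse", "var_delta_ct",
                    "intercept_delta_pse", "intercept_delta_ct"):
            values[lab] = 0.0
        spec = build_bivariate_lcsm(schema)
        mu, sigma = implied_moments(spec, values)
        n_ind = len(schema.indicators)
        t1 = list(range(n_ind)) + [2 * n_ind]
        t2 = list(range(n_ind, 2 * n_ind)) + [2 * n_ind + 1]
        assert np.allclose(mu[t1], mu[t2])
        assert np.allclose(sigma[np.ix_(t1, t1)], sigma[np.ix_(t2, t2)])


class TestMultigroup:
    def test_toggling_change_covariance_changes_df_by_groups_minus_one(self, schema):
        base = build_bivariate_lcsm(schema)
        four = ["female_early", "female_nonearly", "male_early", "male_nonearly"]
        free = expand_multigroup(base, four, frozenset())
        cons = expand_multigroup(base, four, frozenset({"change_covariance"}))
        assert free.n_free - cons.n_free == 3
        two = expand_multigroup(base, ["high", "low"], frozenset())
        two_c = expand_multigroup(base, ["high", "low"], frozenset({"change_covariance"}))
        assert two.n_free - two_c.n_free == 1

    def test_weak_cross_group_invariance_shares_loadings_only(self, schema):
        base = build_longitudinal_cfa(schema, "strong")
        mg = expand_multigroup(base, ["a", "b"], frozenset(), "weak")
        labels = mg.free_labels()
        shared = [lab for lab in labels if "@" not in lab]
        assert all(lab.startswith("lam_") for lab in shared)
        assert len(shared) == len(schema.indicators) - 1

    def test_fully_constrained_multigroup_equals_pooled_fit(self, fast_options):
        spec = build_univariate_lcsm("x", "y")
        rng = np.random.default_rng(31)
        mu = np.array([50.0, 45.0, 30.0, 33.0])
        a = rng.standard_normal((4, 4))
        sigma = a @ a.T + 4 * np.eye(4)
        data = make_exact_moments_data(mu, sigma, 400, names=spec.observed_names)
        pooled = fit_model(spec, data, fast_options)
        half = ["g1"] * 200 + ["g2"] * 200
        data_mg = data.copy()
        data_mg["group"] = half
        mg_spec = expand_multigroup(spec, ["g1", "g2"], frozenset(spec.free_labels()))
        mg = fit_model(mg_spec, data_mg, fast_options)
        for lab in spec.free_labels():
            assert mg.estimates[lab] == pytest.approx(pooled.estimates[lab], abs=2e-3)

    def test_validation_errors(self, schema):
        base = build_bivariate_lcsm(schema)
        with pytest.raises(ModelError, match="non-empty"):
            expand_multigroup(base, [])
        with pytest.raises(ModelError, match="constrained_labels"):
            expand_multigroup(base, ["a", "b"], frozenset({"nope"}))
        with pytest.raises(ModelError, match="already multi-group"):
            expand_multigroup(expand_multigroup(base, ["a", "b"]), ["c"])
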