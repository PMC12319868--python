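"""Synthetic-cohort generator: canonical truth, moments, and missingness."""

import numpy as np
import pandas as pd
import pytest

from latentchange.model import ModelError
from latentchange.simulate import (
    GeneratingParams,
    MissingnessParams,
    StructuralParams,
    canonical_params,
    implied_moments_from_params,
    inject_missingness,
    simulate_dataset,
)


class TestCanonicalParams:
    def test_structural_anchors(self, canonical):
        s = canonical.structural
        assert s.change_covariance == 2.62
        assert s.self_feedback_pse == -0.51
        assert s.self_feedback_ct == -0.16
        assert s.coupling_pse_ct == -0.01
        assert s.baseline_covariance == -0.18
        assert s.mean_pse_t1 == 80.74
        assert s.mean_ct_t1 == 57.14

    def test_baseline_variances_back_solved_from_variance_proportions(self, canonical):
        s = canonical.structural
        total_dpse = s.self_feedback_pse**2 * s.var_pse_t1 + s.var_delta_pse
        assert s.var_delta_pse / total_dpse == pytest.approx(0.74, abs=1e-9)
        total_dct = (
            s.self_feedback_ct**2 * s.var_ct_t1
            + s.coupling_pse_ct**2 * s.var_pse_t1
            + 2 * s.self_feedback_ct * s.coupling_pse_ct * s.baseline_covariance
            + s.var_delta_ct
        )
        assert s.var_delta_ct / total_dct == pytest.approx(0.91, abs=1e-9)
        assert total_dct == pytest.approx(35.28 / 0.91, abs=1e-9)

    def test_low_loading_calibration(self, canonical):
        s = canonical.structural
        sd_pse = np.sqrt(s.var_pse_t1)
        for ind, target in (("friends", 0.10), ("neigh_safety", 0.20), ("family_coh", 0.26)):
            mp = canonical.measurement[ind]
            sd_obs = np.sqrt(mp.loading**2 * s.var_pse_t1 + mp.resid_var)
            assert mp.loading * sd_pse / sd_obs == pytest.approx(target, abs=1e-9)

    def test_non_pd_truth_rejected_at_construction(self):
        s = StructuralParams(var_pse_t1=1.0, baseline_covariance=50.0)
        with pytest.raises(ModelError, match="positive definite"):
            GeneratingParams(structural=s)

    def test_yaml_round_trip(self, canonical, tmp_path):
        path = tmp_path / "truth.yaml"
        canonical.to_yaml(path)
        loaded = GeneratingParams.from_yaml(path)
        assert loaded.to_dict() == canonical.to_dict()
        a = simulate_dataset(canonical, 50, seed=1)
        b = simulate_dataset(loaded, 50, seed=1)
        pd.testing.assert_frame_equal(a, b)


class TestSimulation:
    def test_same_seed_is_byte_identical(self, canonical):
        a = simulate_dataset(canonical, 300, seed=42, include_demographics=True)
        b = simulate_dataset(canonical, 300, seed=42, include_demographics=True)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, canonical):
        a = simulate_dataset(canonical, 50, seed=1)
        b = simulate_dataset(canonical, 50, seed=2)
        assert not a.drop(columns="subject_id").equals(b.drop(columns="subject_id"))

    def test_large_sample_moments_converge_to_implied(self, canonical):
        mu, sigma = implied_moments_from_params(canonical)
        n = 120_000
        df = simulate_dataset(canonical, n, seed=17)
        cols = [c for c in df.columns if c != "subject_id"]
        x = df[cols].to_numpy()
        xbar = x.mean(axis=0)
        s_hat = np.cov(x.T, bias=True)
        # elementwise: |error| < 3 SE of the corresponding sample moment
        se_mean = np.sqrt(np.diag(sigma) / n)
        assert np.all(np.abs(xbar - mu) < 3.3 * se_mean)
        d = np.sqrt(np.diag(sigma))
        se_cov = np.sqrt((np.outer(d, d) ** 2 + sigma**2) / n)
        assert np.all(np.abs(s_hat - sigma) < 3.3 * se_cov)

    def test_column_means_near_published_intercepts(self, canonical):
        df = simulate_dataset(canonical, 60_000, seed=18)
        assert df["school_env_t1"].mean() == pytest.approx(80.74, abs=0.25)
        assert df["ct_t1"].mean() == pytest.approx(57.14, abs=0.25)


class TestMissingness:
    def test_rate_zero_leaves_table_unchanged(self, canonical):
        df = simulate_dataset(canonical, 200, seed=3)
        params = canonical_params()
        params.missingness = MissingnessParams(ct_t2_rate=0.0, indicator_t2_rate=0.0)
        out = inject_missingness(df, params, seed=4)
        pd.testing.assert_frame_equal(out, df)

    def test_rate_one_blanks_the_column(self, canonical):
        df = simulate_dataset(canonical, 100, seed=3)
        params = canonical_params()
        params.missingness = MissingnessParams(ct_t2_rate=1.0, indicator_t2_rate=0.0)
        out = inject_missingness(df, params, seed=4)
        assert out["ct_t2"].isna().all()
        assert out["prosocial_t2"].notna().all()

    def test_invalid_rate_rejected(self):
        with pytest.raises(ModelError, match="outside"):
            MissingnessParams(ct_t2_rate=1.2).validate()

    def test_realized_rates_match_targets(self, canonical):
        n = 20_000
        df = simulate_dataset(canonical, n, seed=5)
        out = inject_missingness(df, canonical, seed=6)
        for col, rate in (("ct_t2", 0.20), ("prosocial_t2", 0.10)):
            realized = out[col].isna().mean()
            assert realized == pytest.approx(rate, abs=3.5 * np.sqrt(rate * (1 - rate) / n))
        assert out["ct_t1"].notna().all()

    def test_mar_mechanism(self, canonical):
        """Missingness tracks the observed baseline score, and conditional on
        it is independent of the (pre-deletion) wave-2 brain value."""
        n = 40_000
        df = simulate_dataset(canonical, n, seed=7)
        out = inject_missingness(df, canonical, seed=8)
        miss = out["ct_t2"].isna().to_numpy(float)
        wave1 = [c for c in df.columns if c.endswith("_t1") and c != "ct_t1"]
        score = df[wave1].mean(axis=1).to_numpy()
        z = (score - score.mean()) / score.std()
        ct2 = df["ct_t2"].to_numpy()
        ct2z = (ct2 - ct2.mean()) / ct2.std()
        # marginal dependence on the baseline score (negative slope)
        assert np.corrcoef(miss, z)[0, 1] < -0.02
        # partial regression: coefficient on the true ct_t2 is null
        x = np.column_stack([np.ones(n), z, ct2z])
        beta, *_ = np.linalg.lstsq(x, miss, rcond=None)
        resid = miss - x @ beta
        cov_inv = np.linalg.inv(x.T @ x)
        se = np.sqrt(cov_inv[2, 2] * resid.var() * n / (n - 3))
        assert abs(beta[2]) < 3.5 * se
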