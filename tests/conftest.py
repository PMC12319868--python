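import numpy as np
import pandas as pd
import pytest

from latentchange import (
    FitOptions,
    MeasurementSchema,
    build_bivariate_lcsm,
    canonical_params,
    fit_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def schema():
    return MeasurementSchema()


@pytest.fixture(scope="session")
def canonical():
    return canonical_params()


@pytest.fixture(scope="session")
def cohort(canonical):
    """Complete canonical synthetic cohort, shared across tests."""
    return simulate_dataset(canonical, 2000, seed=11)


@pytest.fixture(scope="session")
def lcsm_fit(cohort, schema):
    """Bivariate LCSM fitted to the shared cohort, with SEs and baselines."""
    fit = fit_model(build_bivariate_lcsm(schema), cohort)
    assert fit.converged
    return fit


def make_exact_moments_data(mu, sigma, n, seed=0, names=None):
    """A sample whose mean and (biased) covariance equal mu/sigma exactly.

    Lets closed-form ML solutions be asserted to optimizer tolerance.
    """
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    p = len(mu)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, p))
    z -= z.mean(axis=0)
    chol_sample = np.linalg.cholesky(np.cov(z.T, bias=True).reshape(p, p))
    z = z @ np.linalg.inv(chol_sample).T @ np.linalg.cholesky(sigma).T + mu
    names = names or [f"y{i}" for i in range(p)]
    return pd.DataFrame(z, columns=names)


@pytest.fixture()
def fast_options():
    return FitOptions(se="none", compute_baselines=False)
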