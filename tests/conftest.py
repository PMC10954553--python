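import numpy as np
import pandas as pd
import pytest

from cndd.mortality import MortalityModelFit, LinearTerm, fit_mortality_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_linear_cloglog_data(n=2500, beta0=-3.2, beta_con=0.002, beta_tot=-1e-5,
                             beta_dbh=-0.02, seed=0):
    """Observations from an exactly linear cloglog truth."""
    r = np.random.default_rng(seed)
    conD = r.gamma(2.0, 60.0, n)
    totD = r.gamma(3.0, 250.0, n)
    dbh = r.uniform(1.0, 10.0, n)
    dt = r.uniform(4.0, 6.0, n)
    eta = beta0 + beta_con * conD + beta_tot * totD + beta_dbh * dbh + np.log(dt)
    p = -np.expm1(-np.exp(eta))
    y = (r.uniform(size=n) < p).astype(int)
    return pd.DataFrame({"Y": y, "dt": dt, "conD": conD, "totD": totD, "dbh": dbh})


def make_parametric_fit(beta0=-3.9, beta_con=0.002, beta_tot=0.0, beta_dbh=0.0,
                        cov_scale=0.0):
    """A purely parametric (linear-term) fit with hand-chosen coefficients."""
    terms = [LinearTerm("conD", 0.0, 1.0), LinearTerm("totD", 0.0, 1.0),
             LinearTerm("dbh", 0.0, 1.0)]
    beta = np.array([beta0, beta_con, beta_tot, beta_dbh])
    cov = cov_scale * np.eye(4)
    return MortalityModelFit(terms=terms, beta=beta, cov=cov,
                             lambdas=np.zeros(0), census_levels=None,
                             sigma_u=np.nan, loglik=np.nan, reml=np.nan,
                             converged=True, auc=np.nan, edf=4.0, n_obs=0)


@pytest.fixture(scope="session")
def linear_data():
    return make_linear_cloglog_data()


@pytest.fixture(scope="session")
def linear_fit(linear_data):
    fit = fit_mortality_model(linear_data)
    assert fit.converged
    return fit
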