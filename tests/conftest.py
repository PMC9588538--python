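import numpy as np
import pandas as pd
import pytest

import riaftbart as rb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_lognormal_data(n=300, K=5, sigma=0.5, tau=0.6, censor_frac=0.3,
                        arm_effects=(0.4, 0.0, -0.4), seed=0):
    """Small clustered lognormal AFT data set with known generating values."""
    rng = np.random.default_rng(seed)
    cluster = 1 + np.arange(n) % K
    x = rng.standard_normal((n, 3))
    a = rng.integers(1, 4, n)
    b_k = rng.normal(0, tau, K)
    eff = np.asarray(arm_effects)
    f_true = 2.0 + 0.6 * x[:, 0] + eff[a - 1]
    logT = f_true + b_k[cluster - 1] + sigma * rng.standard_normal(n)
    T = np.exp(logT)
    if censor_frac > 0:
        rate = rb.calibrate_censoring_rate(T, censor_frac)
        C = rng.exponential(1 / rate, n)
    else:
        C = np.full(n, np.inf)
    y = np.minimum(T, C)
    delta = (T < C).astype(int)
    data = rb.ClusteredSurvivalData(y=y, delta=delta, a=a, cluster=cluster, x=x)
    return data, {"sigma": sigma, "tau": tau, "b_k": b_k, "f_true": f_true,
                  "arm_effects": eff}


@pytest.fixture(scope="session")
def small_fit():
    """One short riAFT-BART fit shared across read-only tests."""
    data, truth = make_lognormal_data(n=300, K=5, seed=3)
    res = rb.RiAFTBART(data, n_trees=30).fit(draws=150, burn=80, seed=7)
    return data, truth, res


def make_results(f_draws, treatments, b_draws=None, sigma2_draws=None,
                 tau2_draws=None, alpha_draws=None, cluster0=None, a_labels=None,
                 mu_hat=0.0):
    """Assemble a RiAFTBARTResults directly from fabricated draws (oracle tests)."""
    D, J, n = f_draws.shape
    K = 2
    cent = rb.CenteringResult(mu_hat=mu_hat, sigma_hat=1.0, y_cent=np.ones(n))
    return rb.RiAFTBARTResults(
        model=None, centering=cent, hyper=None,
        f_draws=np.asarray(f_draws, float),
        b_draws=b_draws if b_draws is not None else np.zeros((D, K)),
        tau2_draws=tau2_draws if tau2_draws is not None else np.ones(D),
        alpha_draws=alpha_draws if alpha_draws is not None else np.ones(D),
        sigma2_draws=sigma2_draws if sigma2_draws is not None else np.ones(D),
        treatments=np.asarray(treatments),
        cluster0=cluster0 if cluster0 is not None else np.zeros(n, dtype=int),
        meta={}, a_labels=a_labels if a_labels is not None
        else np.resize(np.asarray(treatments), n))
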