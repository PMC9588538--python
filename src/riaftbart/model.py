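"""Random-intercept AFT model with a BART regression function.

The model for subject i in cluster k with treatment A and covariates X is

    log T_ik = f(A_ik, X_ik) + b_k + eps_ik,
    b_k ~ N(0, alpha * tau^2),   eps_ik ~ N(0, sigma^2),

where f is a sum of H regularized regression trees, b_k is a cluster-specific
intercept on the log-time scale (months), and alpha is a redundant
parameter-expansion scalar that improves MCMC mixing of tau^2.  Right-censored
subjects are handled by data augmentation: their latent log failure times are
drawn each iteration from the normal conditional truncated to lie above the
censoring point.

Fitting follows the statsmodels idiom: build a :class:`RiAFTBART` model from a
:class:`~riaftbart.data.ClusteredSurvivalData` (or via
:meth:`RiAFTBART.from_dataframe`), call :meth:`~RiAFTBART.fit`, and work with
the returned :class:`RiAFTBARTResults`.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .data import ClusteredSurvivalData, from_dataframe as _data_from_dataframe
from .forest import BARTHyperparams, Forest, update_forest, update_sigma2


# --------------------------------------------------------------------------
# truncated-normal sampling (lower truncation)
# --------------------------------------------------------------------------

def sample_truncated_normal_lower(mean, sd, lower, rng: np.random.Generator) -> np.ndarray:
    """Vectorized draws from N(mean, sd^2) truncated to (lower, inf).

    Inverse-CDF sampling in the body; for standardized truncation points
    beyond 5 SDs an exponential-rejection tail sampler (Robert 1995) is used
    for numerical stability.
    """
    mean, sd, lower = np.broadcast_arrays(
        np.atleast_1d(np.asarray(mean, dtype=float)),
        np.asarray(sd, dtype=float), np.asarray(lower, dtype=float))
    mean = mean.astype(float)
    sd = sd.astype(float)
    lower = lower.astype(float)
    a = (lower - mean) / sd
    out = np.empty_like(mean)

    body = a <= 5.0
    if body.any():
        ab = a[body]
        pa = special.ndtr(ab)
        u = rng.random(ab.shape)
        q = pa + u * (1.0 - pa)
        out[body] = special.ndtri(np.clip(q, 1e-16, 1 - 1e-16))
    tail = ~body
    if tail.any():
        at = a[tail]
        lam = 0.5 * (at + np.sqrt(at * at + 4.0))
        x = np.empty_like(at)
        todo = np.ones(at.shape, dtype=bool)
        while todo.any():
            m = int(todo.sum())
            prop = at[todo] - np.log(rng.random(m)) / lam[todo]
            acc = rng.random(m) <= np.exp(-0.5 * (prop - lam[todo]) ** 2)
            idx = np.flatnonzero(todo)
            x[idx[acc]] = prop[acc]
            todo[idx[acc]] = False
        out[tail] = x
    return mean + sd * out


# --------------------------------------------------------------------------
# response centering
# --------------------------------------------------------------------------

@dataclass
class CenteringResult:
    """Intercept-only censored-lognormal fit used to center the responses.

    mu_hat : intercept on the log-month scale (added back to posterior f draws).
    sigma_hat : residual scale; sets the leaf-prior scale xi = 4 * sigma_hat.
    y_cent : centered times y * exp(-mu_hat).
    """

    mu_hat: float
    sigma_hat: float
    y_cent: np.ndarray


def center_responses(data: ClusteredSurvivalData) -> CenteringResult:
    """ML fit of the intercept-only lognormal AFT model with right censoring."""
    if data.delta.sum() < 1:
        raise ValueError("all subjects censored: intercept-only lognormal MLE is unbounded")
    from lifelines import LogNormalFitter

    lnf = LogNormalFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lnf.fit(data.y, event_observed=data.delta)
    mu_hat = float(lnf.mu_)
    sigma_hat = float(lnf.sigma_)
    return CenteringResult(mu_hat=mu_hat, sigma_hat=sigma_hat,
                           y_cent=data.y * np.exp(-mu_hat))


def _aft_linear_residuals(data: ClusteredSurvivalData) -> np.ndarray:
    """Residuals log y - X beta from a parametric lognormal AFT with linear X.

    Falls back to intercept-only residuals (with a warning) when the design is
    singular or the fit fails.
    """
    from lifelines import LogNormalAFTFitter

    df = data.x.copy().reset_index(drop=True)
    df["_t"] = data.y
    df["_e"] = data.delta
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aft = LogNormalAFTFitter(penalizer=1e-6)
            aft.fit(df, duration_col="_t", event_col="_e")
        mu = np.log(aft.predict_median(df).to_numpy())
        return np.log(data.y) - mu
    except Exception:  # singular design, separation, convergence failure
        warnings.warn("linear lognormal AFT failed; falling back to intercept-only residuals")
        cent = center_responses(data)
        return np.log(data.y) - cent.mu_hat


def solve_lambda(sigma0: float, nu: float, prob: float = 0.9) -> float:
    """lambda such that P(sigma < sigma0) = prob under sigma^2 ~ IG(nu/2, nu*lambda/2).

    Closed form via the regularized upper incomplete gamma inverse:
    P(sigma^2 < s) = Q(nu/2, nu*lambda/(2s)), so
    lambda = 2 * sigma0^2 * Q^{-1}(nu/2, prob) / nu.
    """
    if sigma0 <= 0 or nu <= 0:
        raise ValueError("sigma0 and nu must be positive")
    return 2.0 * sigma0 ** 2 * float(special.gammainccinv(nu / 2.0, prob)) / nu


# --------------------------------------------------------------------------
# sampler state and conditional updates
# --------------------------------------------------------------------------

@dataclass
class SamplerState:
    """Current MCMC state: forest, cluster intercepts, variance components and
    the imputed complete-data centered log times z."""

    forest: Forest
    b: np.ndarray
    tau2: float
    alpha: float
    sigma2: float
    z: np.ndarray


def update_random_intercepts(z: np.ndarray, f: np.ndarray, cluster0: np.ndarray,
                             n_clusters: int, tau2: float, alpha: float,
                             sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw b_k ~ N( w S_k / (n_k w + sigma^2), sigma^2 w / (n_k w + sigma^2) )
    with w = tau^2 * alpha and S_k the within-cluster sum of z - f."""
    resid = z - f
    nk = np.bincount(cluster0, minlength=n_clusters)
    s = np.bincount(cluster0, weights=resid, minlength=n_clusters)
    w = tau2 * alpha
    denom = nk * w + sigma2
    mean = w * s / denom
    var = sigma2 * w / denom
    return mean + np.sqrt(var) * rng.standard_normal(n_clusters)


def update_alpha(b: np.ndarray, tau2: float, rng: np.random.Generator) -> float:
    """Parameter-expansion scalar: alpha | b, tau2 ~ IG(K/2 + 1, 1 + sum b^2/(2 tau^2)).

    The shape K/2 + 1 is the conjugate conditional under the IG(1, 1) prior
    and the N(0, alpha tau^2) intercept model; it is the unique form under
    which the joint Gibbs chain leaves the prior invariant.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    k = b.size
    scale = 1.0 + float(b @ b) / (2.0 * tau2)
    return scale / rng.gamma(k / 2.0 + 1.0)


def update_tau2(b: np.ndarray, alpha: float, rng: np.random.Generator) -> float:
    """tau^2 | b, alpha ~ IG(K/2 + 1, sum b^2/(2 alpha) + 1)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    k = b.size
    scale = float(b @ b) / (2.0 * alpha) + 1.0
    return scale / rng.gamma(k / 2.0 + 1.0)


def impute_censored(state: SamplerState, log_ycent: np.ndarray, censored: np.ndarray,
                    cluster0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace z for censored subjects with truncated-normal draws (in place).

    Event subjects keep z = log y_cent; censored subjects draw from
    N(f + b_k, sigma^2) truncated to (log y_cent, inf).
    """
    if censored.any():
        mean = state.forest.total_fit[censored] + state.b[cluster0[censored]]
        state.z[censored] = sample_truncated_normal_lower(
            mean, np.sqrt(state.sigma2), log_ycent[censored], rng)
    return state.z


# --------------------------------------------------------------------------
# design-matrix construction: treatment as categorical predictor
# --------------------------------------------------------------------------

def build_design(x: np.ndarray, a: np.ndarray, treatments: np.ndarray) -> np.ndarray:
    """Covariates with one indicator column appended per treatment arm."""
    x = np.asarray(x, dtype=float)
    ind = np.column_stack([(a == t).astype(float) for t in treatments])
    return np.column_stack([x, ind])


def counterfactual_design(x: np.ndarray, arm_index: int, n_treatments: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    ind = np.zeros((x.shape[0], n_treatments))
    ind[:, arm_index] = 1.0
    return np.column_stack([x, ind])


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class RiAFTBART:
    """Random-intercept AFT-BART model for clustered multi-treatment survival data.

    Parameters
    ----------
    data : ClusteredSurvivalData
        Validated clustered survival data.
    n_trees : int
        Number of trees H in the sum-of-trees regression function.
    k : float
        Leaf-prior shrinkage; k = 2 places ~95% prior mass of f on
        [-2 sigma_hat_aft, 2 sigma_hat_aft].
    nu : float
        Shape hyperparameter of the IG(nu/2, nu*lambda/2) prior on sigma^2;
        lambda is calibrated at initialization so that P(sigma < sigma^(0)) = 0.9.
    """

    def __init__(self, data: ClusteredSurvivalData, n_trees: int = 200,
                 k: float = 2.0, nu: float = 3.0,
                 base: float = 0.95, power: float = 2.0):
        self.data = data
        self.n_trees = int(n_trees)
        self.k = float(k)
        self.nu = float(nu)
        self.base = float(base)
        self.power = float(power)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time: str = "time", event: str = "event",
                       treatment: str = "treatment", cluster: str = "cluster",
                       covariates=None, **kwargs) -> "RiAFTBART":
        data = _data_from_dataframe(df, time=time, event=event, treatment=treatment,
                                    cluster=cluster, covariates=covariates)
        return cls(data, **kwargs)

    # -- initialization (exposed for testing) ---------------------------------
    def initialize_state(self, rng: np.random.Generator,
                         centering: CenteringResult | None = None
                         ) -> tuple[SamplerState, BARTHyperparams, CenteringResult]:
        data = self.data
        cent = centering if centering is not None else center_responses(data)
        resid = _aft_linear_residuals(data)
        cluster0 = data.cluster - 1
        K = data.n_clusters
        b0 = np.bincount(cluster0, weights=resid, minlength=K) / np.bincount(cluster0, minlength=K)
        sigma0 = float(np.std(resid))
        sigma0 = max(sigma0, 1e-6)
        lam = solve_lambda(sigma0, self.nu, 0.9)
        hyper = BARTHyperparams(H=self.n_trees, k=self.k, xi=4.0 * cent.sigma_hat,
                                nu=self.nu, lam=lam, base=self.base, power=self.power)
        log_ycent = np.log(cent.y_cent)
        z = log_ycent.copy()
        censored = data.delta == 0
        z[censored] += 0.1 * sigma0  # any positive offset; resampled at once
        X = build_design(data.x.to_numpy(), data.a, data.treatments)
        forest = Forest(X, hyper.H)
        state = SamplerState(forest=forest, b=b0, tau2=1.0, alpha=1.0,
                             sigma2=sigma0 ** 2, z=z)
        return state, hyper, cent

    # -- the Gibbs loop -------------------------------------------------------
    def fit(self, draws: int = 3500, burn: int = 1000, thin: int = 1,
            seed: int | np.random.Generator = 0,
            keep_forests: bool = False,
            param_expansion: bool = True) -> "RiAFTBARTResults":
        """Run the Metropolis-within-Gibbs sampler and return the posterior.

        One iteration: impute censored log times; one backfitting sweep of the
        forest on z - b; conjugate sigma^2 draw on z - f - b; cluster-intercept
        draws; parameter-expansion alpha draw; tau^2 draw.
        """
        if draws < 1:
            raise ValueError("draws must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        data = self.data
        state, hyper, cent = self.initialize_state(rng)
        cluster0 = data.cluster - 1
        K = data.n_clusters
        censored = data.delta == 0
        log_ycent = np.log(cent.y_cent)
        treatments = data.treatments
        J = len(treatments)
        xmat = data.x.to_numpy()
        cf_designs = [counterfactual_design(xmat, j, J) for j in range(J)]

        n_store = draws
        store_f = np.empty((n_store, J, data.n))
        store_b = np.empty((n_store, K))
        store_scalar = np.empty((n_store, 3))  # tau2, alpha, sigma2
        forests: list = []

        total = burn + draws * thin
        d = 0
        for it in range(total):
            impute_censored(state, log_ycent, censored, cluster0, rng)
            bvec = state.b[cluster0]
            update_forest(state.forest, state.z - bvec, state.sigma2, hyper, rng)
            f = state.forest.total_fit
            state.sigma2 = update_sigma2(state.z - f - bvec, hyper.nu, hyper.lam, rng)
            state.b = update_random_intercepts(state.z, f, cluster0, K,
                                               state.tau2, state.alpha, state.sigma2, rng)
            if param_expansion:
                state.alpha = update_alpha(state.b, state.tau2, rng)
            state.tau2 = update_tau2(state.b, state.alpha, rng)
            if not np.isfinite(state.sigma2) or not np.isfinite(state.tau2):
                raise FloatingPointError(
                    f"numerical overflow at iteration {it}: "
                    f"sigma2={state.sigma2}, tau2={state.tau2}, alpha={state.alpha}")
            if it >= burn and (it - burn) % thin == 0:
                for j in range(J):
                    store_f[d, j] = state.forest.predict(cf_designs[j]) + cent.mu_hat
                store_b[d] = state.b
                store_scalar[d] = (state.tau2, state.alpha, state.sigma2)
                if keep_forests:
                    forests.append(copy.deepcopy(state.forest.trees))
                d += 1
                if d == n_store:
                    break

        return RiAFTBARTResults(
            model=self, centering=cent, hyper=hyper,
            f_draws=store_f, b_draws=store_b,
            tau2_draws=store_scalar[:, 0], alpha_draws=store_scalar[:, 1],
            sigma2_draws=store_scalar[:, 2],
            treatments=treatments, cluster0=cluster0,
            meta={"draws": draws, "burn": burn, "thin": thin,
                  "seed": None if isinstance(seed, np.random.Generator) else int(seed),
                  "n_trees": hyper.H, "k": hyper.k, "nu": hyper.nu, "lam": hyper.lam},
            forests=forests if keep_forests else None,
            state=state)


class RiAFTBARTResults:
    """Posterior draws and causal summaries from a fitted riAFT-BART model.

    ``f_draws[d, j, i]`` is the d-th posterior draw of f(a_j, x_i) on the
    training design, in log-months, with the centering intercept mu_hat added
    back.  Causal contrasts, counterfactual survival curves and RMST live here
    (see :mod:`riaftbart.causal` for the free functions they wrap).
    """

    def __init__(self, model, centering, hyper, f_draws, b_draws, tau2_draws,
                 alpha_draws, sigma2_draws, treatments, cluster0, meta,
                 forests=None, state=None, a_labels=None):
        self.model = model
        self.a_labels = (np.asarray(a_labels) if a_labels is not None
                         else (model.data.a if model is not None else None))
        self.centering = centering
        self.hyper = hyper
        self.f_draws = f_draws
        self.b_draws = b_draws
        self.tau2_draws = tau2_draws
        self.alpha_draws = alpha_draws
        self.sigma2_draws = sigma2_draws
        self.treatments = np.asarray(treatments)
        self.cluster0 = cluster0
        self.meta = dict(meta)
        self.forests = forests
        self.state = state

    # -- basic accessors ------------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.f_draws.shape[0]

    @property
    def mu_hat(self) -> float:
        return self.centering.mu_hat

    def arm_index(self, a) -> int:
        idx = np.flatnonzero(self.treatments == a)
        if idx.size == 0:
            raise ValueError(f"unknown treatment label {a!r}; known: {self.treatments.tolist()}")
        return int(idx[0])

    # -- causal inference (delegates to riaftbart.causal) --------------------
    def predict_counterfactual(self, a, x=None) -> np.ndarray:
        from . import causal
        return causal.predict_counterfactual(self, a, x)

    def cate(self, aj, aj_prime, scale: str = "logtime", t_star: float = 60.0):
        from . import causal
        return causal.estimate_cate(self, aj, aj_prime, scale=scale, t_star=t_star)

    def catt(self, aj, aj_prime, scale: str = "logtime", t_star: float = 60.0):
        from . import causal
        return causal.estimate_catt(self, aj, aj_prime, scale=scale, t_star=t_star)

    def survival_curve(self, a, row: int | None = None, x=None,
                       cluster: int | None = None, t_grid=None):
        from . import causal
        return causal.survival_curve(self, a, row=row, x=x, cluster=cluster, t_grid=t_grid)

    # -- summaries ------------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior means, SDs and 95% equal-tailed intervals for the variance
        components, cluster intercepts and all pairwise log-time CATEs."""
        rows = []

        def add(name, draws, unit):
            q = np.quantile(draws, [0.025, 0.975])
            rows.append({"parameter": name, "mean": np.mean(draws), "sd": np.std(draws),
                         "ci_2.5%": q[0], "ci_97.5%": q[1], "units": unit})

        add("sigma", np.sqrt(self.sigma2_draws), "log-months")
        add("tau", np.sqrt(self.tau2_draws), "log-months")
        add("alpha", self.alpha_draws, "-")
        for k in range(self.b_draws.shape[1]):
            add(f"b[{k + 1}]", self.b_draws[:, k], "log-months")
        for i, aj in enumerate(self.treatments):
            for ajp in self.treatments[i + 1:]:
                r = self.cate(aj, ajp)
                rows.append({"parameter": f"CATE({aj},{ajp})", "mean": r.estimate,
                             "sd": np.std(r.draws), "ci_2.5%": r.ci[0],
                             "ci_97.5%": r.ci[1], "units": "log-months"})
        return pd.DataFrame(rows)

    def diagnostics(self) -> pd.DataFrame:
        """Split-chain R-hat and effective sample size for tau, sigma, alpha, b_k."""
        if self.n_draws < 10:
            raise ValueError("need at least 10 draws for diagnostics")
        import arviz as az

        params = {"tau": np.sqrt(self.tau2_draws), "sigma": np.sqrt(self.sigma2_draws),
                  "alpha": self.alpha_draws}
        for k in range(self.b_draws.shape[1]):
            params[f"b[{k + 1}]"] = self.b_draws[:, k]
        rows = []
        for name, dr in params.items():
            half = dr.size // 2
            two = dr[: 2 * half].reshape(2, half)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(two))
                ess = float(az.ess(two))
            rows.append({"parameter": name, "rhat": rhat, "ess": ess,
                         "mean": float(dr.mean()), "sd": float(dr.std())})
        return pd.DataFrame(rows)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Write the posterior draws to a single .npz container."""
        import json as _json

        def _labels(arr):
            arr = np.asarray(arr)
            return arr.astype(str) if arr.dtype == object else arr

        np.savez_compressed(
            path, f_draws=self.f_draws, b_draws=self.b_draws,
            tau2_draws=self.tau2_draws, alpha_draws=self.alpha_draws,
            sigma2_draws=self.sigma2_draws, treatments=_labels(self.treatments),
            cluster0=self.cluster0, a_labels=_labels(self.a_labels),
            mu_hat=np.array(self.centering.mu_hat),
            sigma_hat=np.array(self.centering.sigma_hat),
            meta=np.frombuffer(_json.dumps(self.meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "RiAFTBARTResults":
        import json as _json

        with np.load(path, allow_pickle=False) as z:
            meta = _json.loads(bytes(z["meta"].tobytes()).decode())
            cent = CenteringResult(mu_hat=float(z["mu_hat"]),
                                   sigma_hat=float(z["sigma_hat"]),
                                   y_cent=np.array([]))
            return cls(model=None, centering=cent, hyper=None,
                       f_draws=z["f_draws"], b_draws=z["b_draws"],
                       tau2_draws=z["tau2_draws"], alpha_draws=z["alpha_draws"],
                       sigma2_draws=z["sigma2_draws"], treatments=z["treatments"],
                       cluster0=z["cluster0"], meta=meta, a_labels=z["a_labels"])

    def trace(self, name: str) -> np.ndarray:
        traces = {"tau2": self.tau2_draws, "sigma2": self.sigma2_draws,
                  "alpha": self.alpha_draws,
                  "tau": np.sqrt(self.tau2_draws), "sigma": np.sqrt(self.sigma2_draws)}
        if name in traces:
            return traces[name]
        if name.startswith("b["):
            k = int(name[2:-1])
            return self.b_draws[:, k - 1]
        raise KeyError(name)
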