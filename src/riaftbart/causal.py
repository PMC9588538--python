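"""Posterior causal inference: counterfactual prediction, CATE/CATT, survival
curves and restricted mean survival time (RMST).

Under consistency, weak unconfoundedness given (X, V), positivity and
covariate-dependent censoring, the average log-time contrast between arms
reduces to E_x[f(a_j, x) - f(a_j', x)]: the cluster intercepts cancel.  The
posterior of the contrast is therefore formed draw-by-draw by averaging the
counterfactual f differences over the empirical covariate distribution.

On the survival-probability or RMST scale the contrast no longer cancels the
cluster intercept; each subject's own cluster intercept draw enters both arms
of the subject-level contrast before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

_SCALES = ("logtime", "surv", "rmst")


@dataclass
class CATEResult:
    """Posterior summary of an averaged pairwise treatment contrast.

    ``draws`` holds the D per-draw averages; ``estimate`` their mean; ``ci``
    the equal-tailed 95% credible interval; ``scale`` one of ``logtime``
    (difference in expected log survival months), ``surv`` (difference in
    survival probability at t*), ``rmst`` (difference in months of restricted
    mean survival up to t*).
    """

    pair: tuple
    draws: np.ndarray
    estimate: float
    ci: tuple
    scale: str
    t_star: float | None = None

    @classmethod
    def from_draws(cls, pair, draws, scale, t_star=None) -> "CATEResult":
        draws = np.asarray(draws, dtype=float)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        return cls(pair=tuple(pair), draws=draws, estimate=float(draws.mean()),
                   ci=(float(lo), float(hi)), scale=scale, t_star=t_star)


def _norm_sf(x):
    return special.ndtr(-x)


# --------------------------------------------------------------------------
# counterfactual prediction
# --------------------------------------------------------------------------

def predict_counterfactual(results, a, x=None) -> np.ndarray:
    """D x n matrix of posterior draws f_d(a, x) in log-months (mu_hat included).

    With ``x=None`` the stored draws on the training design are returned.
    Prediction at new covariate rows requires the fit to have been run with
    ``keep_forests=True``.
    """
    j = results.arm_index(a)
    if x is None:
        return results.f_draws[:, j, :]
    if results.forests is None:
        raise ValueError("prediction at new x requires fit(keep_forests=True)")
    from .forest import Forest
    from .model import counterfactual_design

    x = np.atleast_2d(np.asarray(x, dtype=float))
    design = counterfactual_design(x, j, len(results.treatments))
    out = np.empty((results.n_draws, x.shape[0]))
    for d, trees in enumerate(results.forests):
        pred = np.zeros(x.shape[0])
        for t in trees:
            pred += t.predict(design)
        out[d] = pred + results.mu_hat
    return out


# --------------------------------------------------------------------------
# per-draw, per-subject counterfactual log-time locations
# --------------------------------------------------------------------------

def _locations(results, a, include_b: bool) -> np.ndarray:
    """(D, n) matrix of m_di = f_d(a, x_i) [+ b_{k(i),d}]."""
    j = results.arm_index(a)
    m = results.f_draws[:, j, :]
    if include_b:
        m = m + results.b_draws[:, results.cluster0]
    return m


def _per_draw_contrast(results, aj, aj_prime, scale, t_star, subset=None) -> np.ndarray:
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}")
    if scale == "logtime":
        diff = _locations(results, aj, False) - _locations(results, aj_prime, False)
    else:
        sig = np.sqrt(results.sigma2_draws)[:, None]
        m1 = _locations(results, aj, True)
        m0 = _locations(results, aj_prime, True)
        if scale == "surv":
            diff = lognormal_survival(t_star, m1, sig) - lognormal_survival(t_star, m0, sig)
        else:
            diff = lognormal_rmst(t_star, m1, sig) - lognormal_rmst(t_star, m0, sig)
    if subset is not None:
        diff = diff[:, subset]
    return diff.mean(axis=1)


def estimate_cate(results, aj, aj_prime, scale: str = "logtime",
                  t_star: float = 60.0) -> CATEResult:
    """Conditional average treatment effect of a_j vs a_j', averaged over the
    empirical distribution of all N subjects' covariates."""
    draws = _per_draw_contrast(results, aj, aj_prime, scale, t_star)
    return CATEResult.from_draws((aj, aj_prime), draws, scale, t_star if scale != "logtime" else None)


def estimate_catt(results, aj, aj_prime, scale: str = "logtime",
                  t_star: float = 60.0) -> CATEResult:
    """CATT: as :func:`estimate_cate` but averaging over subjects who actually
    received the reference treatment a_j."""
    subset = np.flatnonzero(results.a_labels == aj)
    if subset.size == 0:
        raise ValueError(f"no subjects received treatment {aj!r}")
    draws = _per_draw_contrast(results, aj, aj_prime, scale, t_star, subset=subset)
    return CATEResult.from_draws((aj, aj_prime), draws, scale, t_star if scale != "logtime" else None)


# --------------------------------------------------------------------------
# survival curves and RMST
# --------------------------------------------------------------------------

def lognormal_survival(t, m, sigma) -> np.ndarray:
    """S(t) = 1 - Phi((log t - m) / sigma), broadcasting over arrays."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        z = (np.log(t) - m) / sigma
    return _norm_sf(z)


def lognormal_rmst(t_star, m, sigma) -> np.ndarray:
    """Closed-form restricted mean survival time of LogNormal(m, sigma^2).

    E[min(T, t*)] = t* (1 - Phi(u)) + exp(m + sigma^2/2) Phi(u - sigma),
    u = (log t* - m)/sigma.
    """
    u = (np.log(t_star) - m) / sigma
    return t_star * _norm_sf(u) + np.exp(m + 0.5 * sigma ** 2) * special.ndtr(u - sigma)


def survival_curve(results, a, row: int | None = None, x=None,
                   cluster: int | None = None, t_grid=None,
                   rng: np.random.Generator | None = None):
    """Per-draw and posterior-mean counterfactual survival on a time grid.

    For a training subject pass ``row`` (its own cluster intercept is used
    unless ``cluster`` overrides it).  With ``cluster=None`` and no row-linked
    cluster, the intercept is marginalized by drawing one new b ~ N(0,
    alpha_d tau2_d) per posterior draw.

    Returns ``(t_grid, per_draw (D x len(t_grid)), posterior_mean)``.
    """
    if t_grid is None:
        t_grid = np.linspace(1e-3, 120.0, 241)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0) or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be positive and increasing")
    j = results.arm_index(a)
    if row is not None:
        f = results.f_draws[:, j, row]
        k = results.cluster0[row] if cluster is None else cluster - 1
        b = results.b_draws[:, k]
    else:
        f = predict_counterfactual(results, a, x)[:, 0]
        if cluster is not None:
            b = results.b_draws[:, cluster - 1]
        else:
            rng = rng or np.random.default_rng(0)
            b = rng.normal(0.0, np.sqrt(results.alpha_draws * results.tau2_draws))
    m = (f + b)[:, None]
    sig = np.sqrt(results.sigma2_draws)[:, None]
    per_draw = lognormal_survival(t_grid[None, :], m, sig)
    return t_grid, per_draw, per_draw.mean(axis=0)


def rmst(surv: np.ndarray, t_grid: np.ndarray, t_star: float) -> float | np.ndarray:
    """Trapezoidal RMST: area under the survival curve from 0 to t*, with
    S(0) = 1 prepended.  ``surv`` may be (len(t_grid),) or (D, len(t_grid))."""
    t_grid = np.asarray(t_grid, dtype=float)
    surv = np.asarray(surv, dtype=float)
    if t_star > t_grid[-1] + 1e-12:
        raise ValueError("t_star beyond the time grid")
    keep = t_grid <= t_star
    tg = t_grid[keep]
    sv = surv[..., keep]
    if tg.size == 0 or tg[-1] < t_star - 1e-12:
        # interpolate the curve at t_star for an exact upper limit
        s_star = np.stack([np.interp(t_star, t_grid, s) for s in np.atleast_2d(surv)])
        s_star = s_star.reshape(surv.shape[:-1] + (1,))
        tg = np.concatenate([tg, [t_star]])
        sv = np.concatenate([sv, s_star], axis=-1)
    tg = np.concatenate([[0.0], tg])
    ones = np.ones(surv.shape[:-1] + (1,))
    sv = np.concatenate([ones, sv], axis=-1)
    out = np.trapezoid(sv, tg, axis=-1)
    return float(out) if out.ndim == 0 else out
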