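"""Logistic mixed-effects model with a single random intercept.

Maximum-likelihood estimation of

    y_ij ~ Bernoulli(p_ij),  logit(p_ij) = x_ij' beta + u_j,
    u_j ~ N(0, sigma^2)  (one intercept per cluster, e.g. per butterfly),

with the marginal likelihood integrated over u by the Laplace
approximation.  For cluster j with conditional log-likelihood l_j(u) and
Fisher weight W_j(u) = sum_i p(1-p),

    log L_j = l_j(u*) - u*^2 / (2 sigma^2) - 0.5 log(1 + sigma^2 W_j(u*)),

where u* maximizes the penalized log-likelihood (found by a damped Newton
iteration, vectorized across clusters).  As sigma -> 0 this reduces
continuously to the ordinary logistic likelihood.  Standard errors for the
fixed effects come from the observed information at the optimum with the
variance parameter held at its estimate (the convention of standard mixed-
model software); Wald statistics are reported as t-statistics with normal
reference, matching how such models are reported in this literature.

A single random intercept makes the Laplace approximation accurate at the
cluster sizes seen here; adaptive quadrature would refine the integral but
is unnecessary for these designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy import stats as sps

__all__ = ["MixedModelFit", "logistic_mixed_fit", "logistic_mixed_nll"]

_SIGMA_TINY = 1e-8


@dataclass(frozen=True)
class MixedModelFit:
    names: tuple
    params: np.ndarray
    se: np.ndarray
    tstats: np.ndarray
    pvalues: np.ndarray
    random_intercept_sd: float
    loglik: float
    link: str
    converged: bool
    n_obs: int
    n_groups: int
    message: str = ""

    def summary_dict(self) -> dict:
        return {
            "link": self.link,
            "converged": self.converged,
            "random_intercept_sd": self.random_intercept_sd,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "fixed_effects": {
                name: {
                    "estimate": float(b),
                    "se": float(s),
                    "t": float(t),
                    "p": float(p),
                }
                for name, b, s, t, p in zip(
                    self.names, self.params, self.se, self.tstats, self.pvalues
                )
            },
        }


def _prepare(y, X, groups):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = _factorize(groups)
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) > 0])
    return y, X, codes, starts


def _factorize(groups):
    groups = np.asarray(groups)
    uniq, codes = np.unique(groups, return_inverse=True)
    return codes, uniq


def _cluster_sum(vals, starts):
    return np.add.reduceat(vals, starts)


def _solve_modes(eta0, y, codes, starts, sigma2, u0=None, tol=1e-10, max_iter=50):
    """Damped Newton for the per-cluster posterior modes u*."""
    m = starts.size
    u = np.zeros(m) if u0 is None else u0.copy()
    for _ in range(max_iter):
        eta = eta0 + u[codes]
        p = special.expit(eta)
        grad = _cluster_sum(y - p, starts) - u / sigma2
        W = _cluster_sum(p * (1.0 - p), starts)
        step = grad / (W + 1.0 / sigma2)
        # dampen large steps for stability under separation
        step = np.clip(step, -4.0, 4.0)
        u += step
        if np.max(np.abs(grad)) < tol:
            break
    return u


def logistic_mixed_nll(beta, sigma, y, X, codes, starts, u_cache=None):
    """Negative Laplace marginal log-likelihood."""
    eta0 = X @ beta
    if sigma < _SIGMA_TINY:
        p = special.expit(eta0)
        ll = np.sum(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300))
        return -ll, np.zeros(starts.size)
    sigma2 = sigma * sigma
    u = _solve_modes(eta0, y, codes, starts, sigma2,
                     u0=None if u_cache is None else u_cache)
    eta = eta0 + u[codes]
    p = special.expit(eta)
    ll_cond = np.sum(y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300))
    W = _cluster_sum(p * (1.0 - p), starts)
    ll = ll_cond - np.sum(u * u) / (2.0 * sigma2) - 0.5 * np.sum(
        np.log1p(sigma2 * W)
    )
    return -ll, u


def logistic_mixed_fit(
    y,
    X,
    groups,
    names=None,
    sigma: float | None = None,
    start_sigma: float = 0.5,
) -> MixedModelFit:
    """Fit the random-intercept logistic model by Laplace ML.

    Parameters
    ----------
    y : binary outcome (0/1) per observation.
    X : design matrix including the intercept column.
    groups : cluster labels (one random intercept per distinct label).
    names : fixed-effect names (default x0..xk).
    sigma : if given, the random-intercept SD is held fixed (0 gives the
        ordinary logistic model); otherwise it is estimated.
    """
    y_, X_, codes, starts = _prepare(y, X, groups)
    k = X_.shape[1]
    if names is None:
        names = tuple(f"x{i}" for i in range(k))
    names = tuple(names)

    # warm start from the ordinary logistic fit
    beta0 = _plain_logistic(y_, X_)
    estimate_sigma = sigma is None

    if estimate_sigma:
        def obj(theta):
            return logistic_mixed_nll(theta[:k], abs(theta[k]), y_, X_, codes, starts)[0]
        x0 = np.r_[beta0, start_sigma]
        bounds = [(None, None)] * k + [(0.0, 25.0)]
    else:
        def obj(theta):
            return logistic_mixed_nll(theta, sigma, y_, X_, codes, starts)[0]
        x0 = beta0
        bounds = [(None, None)] * k

    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
    theta = res.x
    beta = theta[:k]
    sig = abs(theta[k]) if estimate_sigma else float(sigma)
    message = str(res.message)

    def se_for(beta_hat, penalty=0.0):
        def nll_beta(b):
            val = logistic_mixed_nll(b, sig, y_, X_, codes, starts)[0]
            return val + 0.5 * penalty * float(b @ b)

        H = _num_hessian(nll_beta, beta_hat)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full(k, np.nan)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))

    se = se_for(beta)
    ok = bool(np.all(np.isfinite(se)) and np.all(se > 0)
              and np.all(np.abs(beta) < 15.0))
    if not ok:
        # complete (or quasi-) separation: weak Gaussian penalty on beta
        # (prior SD 2.5 on the logit scale) restores a finite optimum
        penalty = 1.0 / 2.5**2

        if estimate_sigma:
            def obj_pen(th):
                val = logistic_mixed_nll(th[:k], abs(th[k]), y_, X_, codes, starts)[0]
                return val + 0.5 * penalty * float(th[:k] @ th[:k])
            x0p = np.r_[np.clip(beta, -5, 5), sig]
            bp = [(None, None)] * k + [(0.0, 25.0)]
        else:
            def obj_pen(th):
                val = logistic_mixed_nll(th, sigma, y_, X_, codes, starts)[0]
                return val + 0.5 * penalty * float(th @ th)
            x0p = np.clip(beta, -5, 5)
            bp = [(None, None)] * k
        res = optimize.minimize(obj_pen, x0p, method="L-BFGS-B", bounds=bp,
                                options={"maxiter": 500, "ftol": 1e-12})
        beta = res.x[:k]
        if estimate_sigma:
            sig = abs(res.x[k])
        se = se_for(beta, penalty=penalty)
        message = "penalized fit (separation)"

    nll, _ = logistic_mixed_nll(beta, sig, y_, X_, codes, starts)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * sps.norm.sf(np.abs(t))
    return MixedModelFit(
        names=names,
        params=beta,
        se=se,
        tstats=t,
        pvalues=p,
        random_intercept_sd=float(sig),
        loglik=float(-nll),
        link="logit",
        converged=bool(res.success and np.all(np.isfinite(se)) and np.all(se > 0)),
        n_obs=int(y_.size),
        n_groups=int(starts.size),
        message=message,
    )


def _plain_logistic(y, X, max_iter=100):
    """Newton IRLS for ordinary logistic regression (warm start / oracle limit)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X + 1e-10 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + np.clip(step, -10, 10)
        if np.max(np.abs(grad)) < 1e-10:
            break
    return beta


def _num_hessian(f, x, h=1e-5):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.zeros((k, k))
    hs = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = hs[i]
            ej = np.zeros(k); ej[j] = hs[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / hs[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * hs[i] * hs[j])
    return H
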