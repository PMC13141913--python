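"""Maximum-likelihood logistic mixed model with a single random intercept.

The marginal likelihood of each group (infant) integrates the Bernoulli
likelihood over the group's Gaussian intercept; the one-dimensional
integrals are evaluated by Gauss-Hermite quadrature, so the fit is a
genuine ML estimate rather than a quasi-likelihood approximation.  Standard
errors come from the numerically differentiated Hessian of the marginal
log-likelihood at the optimum.

This is deliberately minimal: one random intercept, logit link, Wald
inference -- exactly the model the presence/absence screens need.
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp
from scipy.stats import norm

logger = logging.getLogger("phageome")

_MAX_ABS_BETA = 15.0  # beyond this on the logit scale we call it separation


class GlmmFit:
    """Result of a random-intercept logistic fit."""

    def __init__(
        self,
        params: np.ndarray,
        se: np.ndarray,
        names: list[str],
        sigma: float,
        converged: bool,
        n_obs: int,
        penalized: bool = False,
        message: str = "",
    ) -> None:
        self.params = params
        self.se = se
        self.names = names
        self.sigma = sigma
        self.converged = converged
        self.n_obs = n_obs
        self.penalized = penalized
        self.message = message

    @property
    def pvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.se
        return 2.0 * norm.sf(np.abs(z))


def _nll_factory(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    n_nodes: int,
    ridge: float,
):
    nodes, weights = hermgauss(n_nodes)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    sign = 2.0 * y - 1.0  # log p(y|eta) = log_expit(sign * eta)

    def nll(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = X @ beta  # (n,)
        u = np.sqrt(2.0) * sigma * nodes  # (K,)
        # (n, K) log-likelihood of each observation at each quadrature node
        ll_obs = log_expit(sign[:, None] * (eta[:, None] + u[None, :]))
        ll_group = np.zeros((n_groups, ll_obs.shape[1]))
        np.add.at(ll_group, group_idx, ll_obs)
        total = logsumexp(ll_group + log_w[None, :], axis=1).sum()
        if ridge:
            total -= ridge * np.dot(beta, beta)
        return -total

    return nll


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * eps * eps)
    return H


def fit_logistic_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    n_nodes: int = 21,
    ridge: float = 0.0,
) -> GlmmFit:
    """Fit logit(P(y=1)) = X beta + u_g, u_g ~ N(0, sigma^2), by marginal ML.

    ``groups`` is any array of group labels.  On apparent separation
    (diverging coefficients or a non-invertible Hessian) the model is refit
    with a small ridge penalty on the fixed effects and flagged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response is constant; both classes must be present")
    labels, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]

    nll = _nll_factory(X, y, group_idx, labels.size, n_nodes, ridge)
    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.log(0.5)  # start sigma at 0.5
    res = minimize(nll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    theta = res.x
    beta, sigma = theta[:-1], float(np.exp(theta[-1]))

    separated = not np.all(np.isfinite(theta)) or np.abs(beta).max() > _MAX_ABS_BETA
    se = np.full(beta.size, np.nan)
    ok = res.success or res.status == 2  # precision loss still usable
    if not separated:
        H = _numerical_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
            diag = np.diag(cov)[:-1]
            if np.any(diag <= 0):
                separated = True
            else:
                se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            separated = True

    if separated and ridge == 0.0:
        logger.info("glmm: apparent separation, refitting with ridge penalty")
        refit = fit_logistic_random_intercept(
            X, y, groups, names=names, n_nodes=n_nodes, ridge=1e-2
        )
        refit.penalized = True
        refit.converged = False
        refit.message = "separation detected; penalized refit"
        return refit

    return GlmmFit(
        params=beta,
        se=se,
        names=list(names),
        sigma=sigma,
        converged=bool(ok and not separated),
        n_obs=y.size,
        penalized=ridge > 0,
        message=res.message,
    )
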