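"""Binomial mixed model with a scalar random intercept per group.

Marginal maximum likelihood for

    y_gi ~ Binomial(m_gi, p_gi),   logit(p_gi) = x_gi' beta + b_g,
    b_g ~ Normal(0, sigma^2),

with the group integral evaluated by Gauss–Hermite quadrature.  Two
integration schemes are provided:

* ``"agh"`` (default) — adaptive quadrature centred on each group's
  posterior mode with curvature scaling; accurate even for large groups.
  Gradients are finite-difference.
* ``"gh"`` — fixed-node quadrature with an analytic gradient; fast, used in
  simulation inner loops, and accurate for moderate intercept SDs.

Boundary estimates (sigma -> 0) are reported as 0 with a flag, in which case
the fit coincides with ordinary logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import norm

from .exceptions import FitError, InvalidArgumentError

__all__ = ["GlmmFit", "fit_binomial_glmm"]

_SQRT2 = math.sqrt(2.0)
_SIGMA_BOUNDARY = 1e-4


@dataclass
class GlmmFit:
    """Maximum-likelihood fit of the scalar-random-intercept binomial model."""

    names: list[str]
    beta: np.ndarray
    sigma: float
    se: np.ndarray
    sigma_se: float
    loglik: float
    nobs: int
    ngroups: int
    converged: bool
    boundary_sigma: bool
    method: str
    dropped: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        """Number of estimated parameters (coefficients + intercept SD)."""
        return len(self.beta) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, np.nan)

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        q = norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - q * self.se,
                                self.beta + q * self.se])


class _Data:
    """Design sorted by group with segment boundaries for reduceat."""

    def __init__(self, X, y, trials, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        m = (np.ones_like(y) if trials is None
             else np.asarray(trials, dtype=float))
        codes, _ = _factorize(groups)
        order = np.argsort(codes, kind="stable")
        self.X = np.ascontiguousarray(X[order])
        self.y = y[order]
        self.m = m[order]
        self.g = codes[order]
        self.G = int(self.g.max()) + 1
        self.starts = np.searchsorted(self.g, np.arange(self.G))
        self.const = float(np.sum(gammaln(self.m + 1) - gammaln(self.y + 1)
                                  - gammaln(self.m - self.y + 1)))


def _factorize(groups):
    groups = np.asarray(groups)
    uniq, codes = np.unique(groups, return_inverse=True)
    return codes, uniq


def _group_sum(values: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(values, starts, axis=0)


def _nll_gh(theta, d: _Data, t_nodes, logw):
    beta, sigma = theta[:-1], theta[-1]
    eta0 = d.X @ beta
    A = eta0[:, None] + (sigma * _SQRT2) * t_nodes[None, :]
    ll = d.y[:, None] * A - d.m[:, None] * np.logaddexp(0.0, A)
    Lg = _group_sum(ll, d.starts)
    return -(logsumexp(Lg + logw[None, :], axis=1).sum() + d.const)


def _nll_grad_gh(theta, d: _Data, t_nodes, logw):
    beta, sigma = theta[:-1], theta[-1]
    eta0 = d.X @ beta
    A = eta0[:, None] + (sigma * _SQRT2) * t_nodes[None, :]
    ll = d.y[:, None] * A - d.m[:, None] * np.logaddexp(0.0, A)
    Lg = _group_sum(ll, d.starts) + logw[None, :]
    # manual logsumexp/softmax over nodes (hot path)
    Lmax = Lg.max(axis=1)
    E = np.exp(Lg - Lmax[:, None])
    S = E.sum(axis=1)
    Mg = Lmax + np.log(S)
    R = E / S[:, None]                    # per-group node responsibilities
    W = d.y[:, None] - d.m[:, None] * expit(A)
    T = R[d.g] * W
    gbeta = d.X.T @ T.sum(axis=1)
    gsigma = float((T * (_SQRT2 * t_nodes)[None, :]).sum())
    return -(Mg.sum() + d.const), -np.append(gbeta, gsigma)


def _modes(d: _Data, eta0, sigma, n_iter=30):
    """Vectorised Newton search for each group's posterior mode and scale."""
    b = np.zeros(d.G)
    for _ in range(n_iter):
        eta = eta0 + sigma * b[d.g]
        p = expit(eta)
        g1 = sigma * _group_sum(d.y - d.m * p, d.starts) - b
        g2 = -(sigma ** 2) * _group_sum(d.m * p * (1.0 - p), d.starts) - 1.0
        step = g1 / g2
        b = b - np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + sigma * b[d.g]
    p = expit(eta)
    curv = (sigma ** 2) * _group_sum(d.m * p * (1.0 - p), d.starts) + 1.0
    return b, 1.0 / np.sqrt(curv)


def _nll_agh(theta, d: _Data, t_nodes, w_nodes):
    beta, sigma = theta[:-1], theta[-1]
    eta0 = d.X @ beta
    bhat, shat = _modes(d, eta0, sigma)
    nodes = bhat[:, None] + _SQRT2 * shat[:, None] * t_nodes[None, :]  # G,K
    A = eta0[:, None] + sigma * nodes[d.g]
    ll = d.y[:, None] * A - d.m[:, None] * np.logaddexp(0.0, A)
    Lg = _group_sum(ll, d.starts)
    integrand = (np.log(w_nodes)[None, :] + t_nodes[None, :] ** 2
                 + Lg - 0.5 * nodes ** 2 - 0.5 * math.log(2 * math.pi))
    lg = logsumexp(integrand, axis=1) + np.log(_SQRT2 * shat)
    return -(lg.sum() + d.const)


def _drop_deficient(X, names):
    """Drop all-zero and linearly dependent columns (pivoted QR)."""
    X = np.asarray(X, dtype=float)
    keep = [j for j in range(X.shape[1]) if np.any(X[:, j] != 0.0)]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    Xk = X[:, keep]
    if Xk.shape[1]:
        _, r, piv = _qr_pivot(Xk)
        rank = int(np.sum(np.abs(np.diag(r)) >
                          1e-9 * max(1.0, abs(r[0, 0]) if r.size else 1.0)))
        if rank < Xk.shape[1]:
            redundant = sorted(piv[rank:])
            dropped += [names[keep[j]] for j in redundant]
            keep = [keep[j] for j in range(len(keep)) if j not in redundant]
            Xk = X[:, keep]
    kept_names = [names[j] for j in keep]
    return Xk, kept_names, dropped


def _qr_pivot(X):
    from scipy.linalg import qr
    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def fit_binomial_glmm(
    X,
    y,
    groups,
    trials=None,
    names=None,
    method: str = "agh",
    n_quad: int = 25,
    start: np.ndarray | None = None,
    compute_se: bool = True,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GlmmFit:
    """Fit the scalar-random-intercept binomial GLMM by marginal ML.

    ``X`` must include an intercept column if one is wanted.  ``start`` is a
    warm-start vector ``[beta..., sigma]`` matching the *kept* columns.
    Rank-deficient columns are dropped with their names recorded on the fit.
    """
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or len(names) != X.shape[1]:
        raise InvalidArgumentError("design/names mismatch")
    Xk, kept, dropped = _drop_deficient(X, list(names))
    d = _Data(Xk, y, trials, groups)
    p = Xk.shape[1]

    t_nodes, w_nodes = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w_nodes) - 0.5 * math.log(math.pi)

    if start is not None and len(start) == p + 1:
        x0 = np.asarray(start, dtype=float).copy()
        x0[-1] = max(x0[-1], 0.0)
    else:
        x0 = np.zeros(p + 1)
        x0[-1] = 0.5
        # logistic-regression-ish start for the intercept column if present
        ybar = min(max(d.y.sum() / d.m.sum(), 1e-4), 1 - 1e-4)
        for j in range(p):
            if np.all(Xk[:, j] == 1.0):
                x0[j] = math.log(ybar / (1 - ybar))
                break

    bounds = [(None, None)] * p + [(0.0, 20.0)]
    if method == "gh":
        fun = lambda th: _nll_grad_gh(th, d, t_nodes, logw)
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter, "ftol": tol,
                                "gtol": 1e-7})
    elif method == "agh":
        fun = lambda th: _nll_agh(th, d, t_nodes, w_nodes)
        res = minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter, "ftol": tol,
                                "gtol": 1e-7})
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")

    theta = res.x
    sigma = float(theta[-1])
    boundary = sigma < _SIGMA_BOUNDARY
    loglik = -float(res.fun)

    se = np.full(p, np.nan)
    sigma_se = float("nan")
    if compute_se:
        H = _hessian(theta, d, t_nodes, logw, w_nodes, method)
        se, sigma_se = _wald_se(H, boundary)
    return GlmmFit(names=kept, beta=theta[:-1].copy(), sigma=sigma, se=se,
                   sigma_se=sigma_se, loglik=loglik, nobs=len(d.y),
                   ngroups=d.G, converged=bool(res.success),
                   boundary_sigma=boundary, method=method, dropped=dropped)


def _hessian(theta, d, t_nodes, logw, w_nodes, method):
    """Central finite-difference Hessian of the negative log-likelihood."""
    k = len(theta)
    if method == "gh":
        grad = lambda th: _nll_grad_gh(th, d, t_nodes, logw)[1]
        g0 = grad(theta)
        H = np.zeros((k, k))
        for j in range(k):
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp = theta.copy()
            tp[j] += h
            H[j] = (grad(tp) - g0) / h
        return 0.5 * (H + H.T)
    f = lambda th: _nll_agh(th, d, t_nodes, w_nodes)
    H = np.zeros((k, k))
    hs = [1e-4 * max(1.0, abs(t)) for t in theta]
    f0 = f(theta)
    for j in range(k):
        for l in range(j, k):
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[j] += hs[j]; tpp[l] += hs[l]
            tpm[j] += hs[j]; tpm[l] -= hs[l]
            tmp[j] -= hs[j]; tmp[l] += hs[l]
            tmm[j] -= hs[j]; tmm[l] -= hs[l]
            clip = lambda th: np.append(th[:-1], max(th[-1], 0.0))
            if j == l:
                H[j, j] = (f(clip(tpp)) - 2 * f0 + f(clip(tmm))) / (
                    (tpp[j] - theta[j]) * (theta[j] - tmm[j]) + 1e-300)
            else:
                H[j, l] = H[l, j] = (
                    f(clip(tpp)) - f(clip(tpm)) - f(clip(tmp)) + f(clip(tmm))
                ) / (4 * hs[j] * hs[l])
    return H


def _wald_se(H, boundary_sigma):
    k = H.shape[0]
    if boundary_sigma:
        sub = H[: k - 1, : k - 1]
        cov = np.linalg.pinv(sub)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        return se, float("nan")
    cov = np.linalg.pinv(H)
    diag = np.clip(np.diag(cov), 0.0, np.inf)
    return np.sqrt(diag[: k - 1]), float(math.sqrt(diag[k - 1]))
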