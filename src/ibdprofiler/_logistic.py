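"""Maximum-likelihood logistic regression via iteratively reweighted
least squares, shared by the GWAS and model-evaluation modules.

Small fixed-width designs (an intercept, a dosage column, ten PCs, a few
factor blocks) fitted many thousands of times dominate the pipeline's
runtime, so the solver is a tight numpy Newton loop rather than a generic
GLM framework.  Fits that fail to converge within ``max_iter`` Newton
steps, or that hit a singular information matrix, are re-fit with a tiny
ridge penalty and flagged ``capped`` — quasi-separated test folds then
still return finite, comparable log-likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LogisticFit", "fit_logistic", "log_likelihood"]

_RIDGE_FALLBACK = 1e-6


@dataclass
class LogisticFit:
    beta: np.ndarray          # coefficient vector, len = n columns of X
    cov: np.ndarray           # inverse observed information (Wald covariance)
    loglik: float             # maximized log-likelihood (unpenalized)
    converged: bool
    capped: bool              # True if the ridge fallback / iteration cap hit
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    """Bernoulli log-likelihood at ``beta`` (numerically stable logsumexp)."""
    eta = X @ beta
    # log(1 + exp(eta)) without overflow
    log1pexp = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
    return float(y @ eta - log1pexp.sum())


def _newton(X, y, ridge, max_iter, tol, beta0):
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else beta0.astype(float).copy()
    ll = log_likelihood(X, y, beta) - 0.5 * ridge * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        info = (X.T * w) @ X + ridge * np.eye(k)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            return beta, ll, False, it, info
        # step-halving line search on the (penalized) likelihood
        for _ in range(25):
            cand = beta + step
            ll_new = log_likelihood(X, y, cand) - 0.5 * ridge * cand @ cand
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            cand, ll_new = beta, ll
        delta = ll_new - ll
        beta, ll = cand, ll_new
        if abs(delta) < tol and np.max(np.abs(grad)) < 1e-4 * (1 + abs(ll)):
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X.T * w) @ X + ridge * np.eye(X.shape[1])
    return beta, ll, converged, it, info


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
    allow_fallback: bool = True,
) -> LogisticFit:
    """Fit ``y ~ X`` by maximum likelihood.

    ``X`` must already contain an intercept column if one is wanted.  On
    non-convergence or a singular information matrix the fit is repeated
    with ridge penalty ``1e-6`` and returned with ``capped=True``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design / response shape mismatch")
    beta, ll_pen, converged, it, info = _newton(X, y, 0.0, max_iter, tol, beta0)
    capped = False
    if not converged and allow_fallback:
        beta, ll_pen, converged, it, info = _newton(
            X, y, _RIDGE_FALLBACK, max_iter, tol, beta
        )
        capped = True
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        capped = True
    ll = log_likelihood(X, y, beta)
    return LogisticFit(beta=beta, cov=cov, loglik=ll, converged=converged,
                       capped=capped, n_iter=it)
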