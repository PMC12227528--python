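"""Compact weighted-least-squares fitters used by the hurdle engine.

The differential-expression pipeline fits tens of thousands of small
logistic/Gaussian regressions (per gene, per resampling repeat, per
permutation); these routines keep per-fit overhead minimal.  The logistic
IRLS is cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logit_fit", "ols_fit", "LogitFitResult", "OLSFitResult"]


class SingularDesignError(np.linalg.LinAlgError):
    pass


class LogitFitResult:
    __slots__ = ("beta", "llf", "converged", "n")

    def __init__(self, beta, llf, converged, n):
        self.beta = beta
        self.llf = llf
        self.converged = converged
        self.n = n


class OLSFitResult:
    __slots__ = ("beta", "llf", "rss", "n")

    def __init__(self, beta, llf, rss, n):
        self.beta = beta
        self.llf = llf
        self.rss = rss
        self.n = n


def _bernoulli_llf(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(y @ np.log(p) + (1.0 - y) @ np.log1p(-p))


def logit_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-9) -> LogitFitResult:
    """Logistic regression by IRLS with step halving.

    Under (quasi-)separation the log-likelihood still converges (to the
    supremum), which is what the likelihood-ratio statistic needs; the
    coefficients are then reported as-is without standard errors.
    """
    n, k = X.shape
    beta = np.zeros(k)
    # intercept-only warm start if first column is constant
    ybar = float(np.mean(y))
    if 0.0 < ybar < 1.0 and np.all(X[:, 0] == X[0, 0]) and X[0, 0] != 0:
        beta[0] = np.log(ybar / (1.0 - ybar)) / X[0, 0]
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    llf = _bernoulli_llf(y, p)
    converged = False
    for _ in range(max_iter):
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-10)
        z = eta + (y - p) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as exc:  # singular weighted design
            raise SingularDesignError(str(exc)) from exc
        step = beta_new - beta
        # step halving on likelihood decrease
        for _ in range(20):
            eta_new = X @ (beta + step)
            p_new = 1.0 / (1.0 + np.exp(-np.clip(eta_new, -35, 35)))
            llf_new = _bernoulli_llf(y, p_new)
            if llf_new >= llf - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        eta, p = X @ beta, p_new
        if abs(llf_new - llf) < tol * (abs(llf) + 1.0):
            llf = llf_new
            converged = True
            break
        llf = llf_new
    return LogitFitResult(beta=beta, llf=llf, converged=converged, n=n)


def ols_fit(X: np.ndarray, y: np.ndarray) -> OLSFitResult:
    """Least squares with the Gaussian profile log-likelihood (MLE variance)."""
    n = X.shape[0]
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesignError(f"design rank {rank} < {X.shape[1]} columns")
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return OLSFitResult(beta=beta, llf=llf, rss=rss, n=n)
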