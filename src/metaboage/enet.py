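"""Elastic net with per-variable penalty multipliers.

Minimizes, over a descending lambda path with warm starts,

    (1/2n) ||y - b0 - X b||^2
        + lambda * sum_j v_j * (alpha |b_j| + (1 - alpha)/2 b_j^2)

via cyclic coordinate descent in covariance form.  ``v_j = 0`` leaves
variable j unshrunk; multipliers are rescaled internally to mean 1 so an
all-equal vector reproduces the unweighted fit exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FitError(ValueError):
    pass


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _cd_solve(G, c, lam, alpha, v, beta, tol=1e-9, max_iter=1000):
    """Coordinate descent on standardized covariances G = X'X/n, c = X'y/n."""
    p = len(c)
    diag = np.diag(G)
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = c[j] - G[j] @ beta + diag[j] * bj
            bnew = _soft(rho, lam * alpha * v[j]) / (diag[j] + lam * (1 - alpha) * v[j])
            if bnew != bj:
                beta[j] = bnew
                max_delta = max(max_delta, abs(bnew - bj))
        if max_delta < tol:
            break
    return beta


@dataclass
class ElasticNetPath:
    lambdas: np.ndarray
    coefs: np.ndarray        # (n_lambda, p) on the original scale
    intercepts: np.ndarray
    cv_mse: np.ndarray | None = None
    lambda_opt: float | None = None


def normalize_penalty_factors(v: np.ndarray, p: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (p,):
        raise FitError("penalty_factors length must match number of predictors")
    if np.any(v < 0):
        raise FitError("penalty_factors must be non-negative")
    s = v.sum()
    if s == 0:
        return v.copy()
    return v * p / s


def lambda_path(X, y, alpha, v, n_lambdas=60, eps=None):
    n, p = X.shape
    c = np.abs(X.T @ (y - y.mean())) / n
    vpos = v > 0
    if not vpos.any():
        return np.array([0.0])
    a = max(alpha, 1e-3)
    lam_max = float(np.max(c[vpos] / (a * v[vpos])))
    lam_max = max(lam_max, 1e-10)
    if eps is None:
        eps = 1e-4 if n > p else 1e-2
    return np.geomspace(lam_max, lam_max * eps, n_lambdas)


def fit_path(X, y, alpha=0.5, penalty_factors=None, lambdas=None, n_lambdas=60):
    """Fit the whole lambda path; coefficients returned on the original scale."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        raise FitError("constant predictor column")
    Z = (X - mu) / sd
    ybar = y.mean()
    yc = y - ybar
    v = (np.ones(p) if penalty_factors is None
         else normalize_penalty_factors(penalty_factors, p))
    if lambdas is None:
        lambdas = lambda_path(Z, y, alpha, v, n_lambdas)
    G = Z.T @ Z / n
    c = Z.T @ yc / n
    beta = np.zeros(p)
    coefs = np.empty((len(lambdas), p))
    intercepts = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        beta = _cd_solve(G, c, lam, alpha, v, beta)
        b_orig = beta / sd
        coefs[i] = b_orig
        intercepts[i] = ybar - mu @ b_orig
    return ElasticNetPath(np.asarray(lambdas, dtype=float), coefs, intercepts)


def cv_fit(
    X,
    y,
    alpha=0.5,
    penalty_factors=None,
    n_folds=10,
    seed=0,
    n_lambdas=60,
    rule="min",
):
    """K-fold CV over the lambda path (MSE); refit on all data at the chosen
    lambda.  ``rule='1se'`` picks the sparsest lambda within one SE of the
    minimum."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    v = (np.ones(p) if penalty_factors is None
         else normalize_penalty_factors(penalty_factors, p))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        raise FitError("constant predictor column")
    lambdas = lambda_path((X - mu) / sd, y, alpha, v, n_lambdas)

    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % n_folds
    err = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        path = fit_path(X[tr], y[tr], alpha, penalty_factors, lambdas=lambdas)
        pred = X[te] @ path.coefs.T + path.intercepts[None, :]
        err[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    mse = err.mean(axis=0)
    i_min = int(np.argmin(mse))
    if rule == "1se":
        se = err.std(axis=0, ddof=1) / np.sqrt(n_folds)
        thresh = mse[i_min] + se[i_min]
        i_min = int(np.argmax(mse <= thresh))  # largest lambda within 1 SE
    path = fit_path(X, y, alpha, penalty_factors, lambdas=lambdas)
    path.cv_mse = mse
    path.lambda_opt = float(lambdas[i_min])
    return path, i_min
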