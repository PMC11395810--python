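"""L1-penalized logistic regression along a regularization path.

glmnet-style fitting: an outer IRLS loop builds a weighted quadratic
approximation to the Bernoulli log-likelihood, and an inner coordinate
descent solves the penalized weighted least-squares problem on
precomputed sufficient statistics (X'WX, X'Wz), so inner sweeps cost
O(p^2) rather than O(np).  Warm-started down a decreasing lambda grid.
The intercept is never penalized and predictors enter on their raw
{0, 1} scale, so coefficients are log-odds interactions.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _soft(z, t):  # pragma: no cover
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=False)
def lasso_logistic_path(X, y, lambdas, tol, max_outer):  # pragma: no cover
    """Fit the full path; returns (coefs, intercepts, logliks).

    ``lambdas`` must be decreasing.  ``tol`` bounds the max coefficient
    change across one IRLS step.  Log-likelihoods are the unpenalized
    Bernoulli log-likelihoods at the penalized estimates.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    coefs = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    logliks = np.zeros(nl)

    ybar = y.mean()
    beta = np.zeros(p)
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)

    A = np.zeros((p, p))     # X'WX / n
    c = np.zeros(p)          # X'Wz / n
    a0 = np.zeros(p)         # X'W1 / n
    w = np.empty(n)
    z = np.empty(n)

    for li in range(nl):
        lam = lambdas[li]
        for _ in range(max_outer):
            # quadratic approximation at the current (b0, beta)
            for i in range(n):
                mu = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = mu * (1.0 - mu)
                if wi < 1e-6:
                    wi = 1e-6
                w[i] = wi
                z[i] = eta[i] + (y[i] - mu) / wi
            wbar = 0.0
            zbar = 0.0
            for i in range(n):
                wbar += w[i]
                zbar += w[i] * z[i]
            wbar /= n
            zbar /= n
            for j in range(p):
                sj = 0.0
                cj = 0.0
                for i in range(n):
                    if X[i, j] != 0.0:
                        sj += w[i] * X[i, j]
                        cj += w[i] * X[i, j] * z[i]
                a0[j] = sj / n
                c[j] = cj / n
                for k in range(j, p):
                    ajk = 0.0
                    for i in range(n):
                        if X[i, j] != 0.0 and X[i, k] != 0.0:
                            ajk += w[i] * X[i, j] * X[i, k]
                    A[j, k] = ajk / n
                    A[k, j] = A[j, k]
            # inner CD on the penalized weighted least squares
            nb0 = b0
            nbeta = beta.copy()
            for _inner in range(10000):
                dmax = 0.0
                s = zbar
                for k in range(p):
                    s -= a0[k] * nbeta[k]
                newb0 = s / wbar
                if newb0 != nb0:
                    dmax = max(dmax, abs(newb0 - nb0))
                    nb0 = newb0
                for j in range(p):
                    r = c[j] - a0[j] * nb0
                    for k in range(p):
                        if k != j:
                            r -= A[j, k] * nbeta[k]
                    new = _soft(r, lam) / max(A[j, j], 1e-10)
                    if new != nbeta[j]:
                        dmax = max(dmax, abs(new - nbeta[j]))
                        nbeta[j] = new
                if dmax < 0.1 * tol:
                    break
            # outer convergence on the coefficient change
            delta = abs(nb0 - b0)
            for j in range(p):
                delta = max(delta, abs(nbeta[j] - beta[j]))
            b0 = nb0
            beta = nbeta
            for i in range(n):
                e = b0
                for j in range(p):
                    if X[i, j] != 0.0 and beta[j] != 0.0:
                        e += X[i, j] * beta[j]
                eta[i] = e
            if delta < tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
        ll = 0.0
        for i in range(n):
            # log sigma(eta) if y=1 else log(1 - sigma(eta)), stably
            if y[i] == 1.0:
                ll -= np.log1p(np.exp(-eta[i]))
            else:
                ll -= np.log1p(np.exp(eta[i]))
        logliks[li] = ll
    return coefs, intercepts, logliks


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                ratio: float = 0.001) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max (all coefficients
    zero) down to ``ratio * lambda_max``."""
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)
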