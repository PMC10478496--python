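"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: closed-form normal
equations for least squares, a bare Newton-Raphson for logistic regression,
and a dense-grid numerical posterior for the single-group ZOIB model.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Least squares via the normal equations, with SEs, t and R^2."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / tss
    return {"beta": beta, "se": se, "t": beta / se, "df": df, "r2": r2}


def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 200):
    """Logistic regression MLE by plain Newton-Raphson."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = expit(X @ beta)
    W = p * (1 - p)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    se = np.sqrt(np.diag(cov))
    return {"beta": beta, "se": se, "z": beta / se}


def grid_posterior_single_group(
    y: np.ndarray,
    sd_alpha: float = np.sqrt(1000.0),
    sd_mu: float = np.sqrt(1000.0),
    sd_phi: float = np.sqrt(100.0),
    n_grid: int = 200,
):
    """Dense-grid posterior for one ZOIB group with gamma pinned at 0.

    Grids cover the transformed scales (logit alpha, logit mu, log phi); wide
    enough that the posterior mass is fully interior for moderate n. Returns
    posterior means of alpha and mu plus the DIC computed on the grid, with
    the plug-in deviance evaluated at the posterior means of the transformed
    parameters (matching the package's convention).
    """
    y = np.asarray(y, float)
    assert not np.any(y == 1.0), "oracle assumes gamma fixed at 0"
    n0 = float(np.sum(y == 0.0))
    interior = y[(y > 0) & (y < 1)]
    n_int = float(interior.size)
    sly = float(np.sum(np.log(interior)))
    sl1y = float(np.sum(np.log1p(-interior)))

    a_grid = np.linspace(-8, 8, n_grid)
    m_grid = np.linspace(-8, 8, n_grid)
    f_grid = np.linspace(-4, 8, n_grid)
    A, M, F = np.meshgrid(a_grid, m_grid, f_grid, indexing="ij")
    al, mu, phi = expit(A), expit(M), np.exp(F)

    def loglik(al, mu, phi):
        return (
            n0 * np.log(al)
            + n_int * np.log1p(-al)
            + n_int * (gammaln(phi) - gammaln(mu * phi) - gammaln((1 - mu) * phi))
            + (mu * phi - 1) * sly
            + ((1 - mu) * phi - 1) * sl1y
        )

    ll = loglik(al, mu, phi)
    lp = ll - 0.5 * (A / sd_alpha) ** 2 - 0.5 * (M / sd_mu) ** 2 - 0.5 * (F / sd_phi) ** 2
    lp -= lp.max()
    w = np.exp(lp)
    w /= w.sum()

    alpha_mean = float((w * al).sum())
    mu_mean = float((w * mu).sum())
    d_bar = float((w * (-2.0 * ll)).sum())
    a_hat, m_hat, f_hat = (float((w * G).sum()) for G in (A, M, F))
    d_hat = float(-2.0 * loglik(expit(a_hat), expit(m_hat), np.exp(f_hat)))
    return {
        "alpha_mean": alpha_mean,
        "mu_mean": mu_mean,
        "d_bar": d_bar,
        "d_hat": d_hat,
        "dic": 2 * d_bar - d_hat,
    }
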