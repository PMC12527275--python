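"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (hand-rolled
IRLS, plain statsmodels fits) and shares no code with the package's own
estimation path.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit


def irls_fluctuation(
    y_star: np.ndarray,
    h1: np.ndarray,
    h0: np.ndarray,
    mu_a: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Newton–Raphson for the intercept-free offset-logistic regression of
    ``y_star`` on ``(h1, h0)`` with offset ``logit(mu_a)``."""
    x = np.column_stack([h1, h0]).astype(float)
    offset = logit(np.asarray(mu_a, dtype=float))
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = offset + x @ beta
        mu = expit(eta)
        grad = x.T @ (y_star - mu)
        w = mu * (1.0 - mu)
        hess = x.T @ (x * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), float(beta[1])


def textbook_tmle(
    y: np.ndarray, a: np.ndarray, x: np.ndarray
) -> float:
    """Hand-coded single-sample (no cross-fit) TMLE with plain GLM nuisances.

    Propensity by statsmodels Logit, outcome by OLS on the min-max scaled
    outcome, fluctuation by :func:`irls_fluctuation`, update scaled by the
    counterfactual clever covariates, and back-transform by the range.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    y_min, y_max = y.min(), y.max()
    y_star = (y - y_min) / (y_max - y_min)

    design_ps = sm.add_constant(x)
    pi = sm.Logit(a, design_ps).fit(disp=0, tol=1e-12).predict(design_ps)
    bound = 5.0 / (np.sqrt(n) * np.log(n))
    pi = np.clip(pi, bound, 1.0 - bound)

    design_out = np.column_stack([np.ones(n), a, x])
    ols = sm.OLS(y_star, design_out).fit()
    lo, hi = 1e-5, 1.0 - 1e-5
    mu1 = np.clip(ols.predict(np.column_stack([np.ones(n), np.ones(n), x])), lo, hi)
    mu0 = np.clip(ols.predict(np.column_stack([np.ones(n), np.zeros(n), x])), lo, hi)
    mu_a = np.where(a == 1, mu1, mu0)

    h1 = a / pi
    h0 = (1.0 - a) / (1.0 - pi)
    eps1, eps0 = irls_fluctuation(y_star, h1, h0, mu_a)
    mu1_u = expit(logit(mu1) + eps1 / pi)
    mu0_u = expit(logit(mu0) + eps0 / (1.0 - pi))
    return float((y_max - y_min) * np.mean(mu1_u - mu0_u))
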