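"""Independent brute-force oracles used by the test suites.

These deliberately avoid the package's own code paths: alignment by
exhaustive rotation search, Bayes factors by dense trapezoidal
quadrature of the explicit integrand, OLS by the normal equations, and
power-based sample size by an exhaustive scan.
"""

import math

import numpy as np
from scipy import stats as sps


def grid_search_distance(A, B, step=1e-4):
    """Partial Procrustes distance by scanning the rotation angle."""
    def unit(X):
        Xc = np.asarray(X, float) - np.asarray(X, float).mean(axis=0)
        return Xc / np.sqrt((Xc**2).sum())

    Za, Zb = unit(A), unit(B)
    thetas = np.arange(0, 2 * np.pi, step)
    c, s = np.cos(thetas), np.sin(thetas)
    # rotate Za by every theta: (T, n, 2)
    x, y = Za[:, 0], Za[:, 1]
    rx = c[:, None] * x - s[:, None] * y
    ry = s[:, None] * x + c[:, None] * y
    d2 = ((rx - Zb[:, 0]) ** 2 + (ry - Zb[:, 1]) ** 2).sum(axis=1)
    return float(np.sqrt(d2.min()))


def jzs_bf_grid(r2, n, p, scale=math.sqrt(2) / 2, nodes=10**6):
    """Model-vs-null JZS Bayes factor by dense trapezoid over log g."""
    if p == 0:
        return 1.0
    u = np.linspace(-40, 40, nodes)
    g = np.exp(u)
    a = n * scale * scale / 2
    log_f = (
        0.5 * (n - 1 - p) * np.log1p(g)
        - 0.5 * (n - 1) * np.log1p(g * (1 - r2))
        + 0.5 * np.log(a)
        - math.lgamma(0.5)
        - 1.5 * u
        - a / g
        + u
    )
    m = log_f.max()
    return float(np.exp(m) * np.trapezoid(np.exp(log_f - m), u))


def r_squared(y, X):
    """R^2 of z-scored OLS, via the normal equations."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    yz = (y - y.mean()) / y.std(ddof=1)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    beta = np.linalg.solve(Z.T @ Z, Z.T @ yz)
    resid = yz - Z @ beta
    return float(1 - resid @ resid / (yz @ yz))


def jzs_effect_bf_grid(y, X, focal_col, scale=math.sqrt(2) / 2, nodes=10**6):
    """Effect-level JZS BF (full vs drop-focal) by grid quadrature."""
    X = np.asarray(X, float)
    n, p = X.shape
    full = jzs_bf_grid(r_squared(y, X), n, p, scale, nodes)
    keep = [j for j in range(p) if j != focal_col]
    if keep:
        reduced = jzs_bf_grid(r_squared(y, X[:, keep]), n, p - 1, scale, nodes)
    else:
        reduced = 1.0
    return full / reduced


def normal_equations_betas(y, X):
    """Standardized OLS betas via an explicit matrix inverse."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    yz = (y - y.mean()) / y.std(ddof=1)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return np.linalg.inv(Z.T @ Z) @ Z.T @ yz


def required_n_scan(f2, alpha=0.05, power=0.80, df1=1, n_predictors=1,
                    n_range=range(10, 201)):
    """Smallest N reaching target power, by direct noncentral-F scan."""
    for n in n_range:
        df2 = n - n_predictors - 1
        if df2 < 1:
            continue
        crit = sps.f.isf(alpha, df1, df2)
        if sps.ncf.sf(crit, df1, df2, f2 * n) >= power:
            return n
    raise ValueError("no N in range reaches the target power")
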