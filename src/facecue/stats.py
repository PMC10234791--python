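"""Statistical engine: winsorisation, correlation, standardized OLS,
JZS default Bayes factors, and noncentral-F power analysis.

The analysis model throughout is a small multiple regression of one
involvement outcome on a focal facial-shape predictor plus an
attractiveness covariate, with every continuous variable winsorised to
+/- 3 SD and z-scored, so coefficients are standardized betas.  Each
focal effect additionally receives a default-prior (Jeffreys-Zellner-
Siow) Bayes factor comparing the model with the predictor to the model
without it; values below 1 favour the null.

The JZS Bayes factor of a linear model against the intercept-only null
uses the Liang et al. (2008) mixture-of-g-priors representation: with
R^2 the model's coefficient of determination on n cases and p
predictors,

    BF10 = int_0^inf (1+g)^((n-1-p)/2) (1 + g(1-R^2))^(-(n-1)/2) pi(g) dg

where g has an inverse-gamma(1/2, n r^2 / 2) prior (Zellner-Siow Cauchy
prior with scale r on standardized slopes).  The integral is evaluated
by adaptive quadrature on the log scale after the substitution
g = exp(u), with the integrand peak-normalised for stability.  An
effect-level Bayes factor is the ratio of the full and reduced models'
BFs against the common intercept-only null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy import stats as sps

__all__ = [
    "EffectResult",
    "PowerSpec",
    "winsorize",
    "pearson",
    "standardized_ols",
    "jzs_bf",
    "bf_against_null",
    "required_n",
    "JZS_DEFAULT_SCALE",
]

JZS_DEFAULT_SCALE = math.sqrt(2) / 2


@dataclass(frozen=True)
class EffectResult:
    """One predictor's standardized effect in one regression model."""

    outcome: str
    predictor: str
    beta: float
    t: float
    df: int
    p: float
    n: int
    bf10: float | None = None

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "beta": self.beta,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "bf10": self.bf10,
            "n": self.n,
        }


@dataclass(frozen=True)
class PowerSpec:
    """A priori power computation for one tested regression term."""

    f2: float
    alpha: float = 0.05
    power: float = 0.80
    df1: int = 1
    n_predictors: int = 2

    def __post_init__(self) -> None:
        if not self.f2 > 0:
            raise ValueError("f2 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.df1 < 1:
            raise ValueError("df1 must be >= 1")


def winsorize(x, k: float = 3.0):
    """Clip values beyond mean +/- k*SD to the threshold.

    Thresholds use the mean and (sample) SD of the ORIGINAL vector in a
    single pass — no re-estimation after clipping.  Missing values pass
    through untouched; a constant vector (SD 0) is returned unchanged.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("winsorize expects a 1-D vector")
    ok = ~np.isnan(arr)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = arr[ok].mean()
    sd = arr[ok].std(ddof=1)
    if sd == 0:
        out = arr.copy()
    else:
        out = np.clip(arr, mean - k * sd, mean + k * sd)
        out[~ok] = np.nan
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


def pearson(x, y) -> tuple[float, int, float]:
    """Product-moment correlation on pairwise-complete cases.

    Returns (r, df, p) with df = n - 2 and the two-sided p value from
    the t transform of r.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    n = xa.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance in a correlation input")
    r, p = sps.pearsonr(xa, ya)
    return float(r), n - 2, float(p)


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance variable in regression")
    return (a - a.mean()) / sd


def standardized_ols(
    y, X: pd.DataFrame, outcome: str = "y"
) -> list[EffectResult]:
    """OLS with all variables z-scored: standardized betas, t, df, p.

    Complete cases only (listwise deletion).  The intercept of the
    standardized model is exactly zero and is not reported.

    Raises on rank-deficient designs and on zero-variance columns.
    """
    X = pd.DataFrame(X)
    ya = np.asarray(y, dtype=float)
    mask = ~np.isnan(ya)
    Xa = X.to_numpy(dtype=float)
    mask &= ~np.isnan(Xa).any(axis=1)
    ya, Xa = ya[mask], Xa[mask]
    n, k = Xa.shape
    if n <= k + 1:
        raise ValueError(f"too few complete cases (n={n}) for {k} predictors")
    yz = _zscore(ya)
    Z = np.column_stack([_zscore(Xa[:, j]) for j in range(k)])
    if np.linalg.matrix_rank(Z) < k:
        raise ValueError("rank-deficient design (collinear predictors)")
    # standardized model: no intercept needed after centering
    beta, _, _, _ = np.linalg.lstsq(Z, yz, rcond=None)
    df = n - k - 1  # intercept counted although it is identically 0
    resid = yz - Z @ beta
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(Z.T @ Z)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    return [
        EffectResult(
            outcome=outcome,
            predictor=col,
            beta=float(beta[j]),
            t=float(t[j]),
            df=int(df),
            p=float(p[j]),
            n=int(n),
        )
        for j, col in enumerate(X.columns)
    ]


def _log_jzs_integrand(u, n: int, p: int, r2: float, scale: float):
    """log of the Liang et al. integrand after g = exp(u) (Jacobian included).

    Written with logaddexp so it stays finite-safe for arbitrarily
    large |u| (it tends to -inf at both ends).
    """
    u = np.asarray(u, dtype=float)
    a = n * scale * scale / 2.0
    with np.errstate(over="ignore"):
        inv_g = np.exp(-u)  # harmless overflow -> inf -> log_prior = -inf
    log_prior = 0.5 * math.log(a) - math.lgamma(0.5) - 1.5 * u - a * inv_g
    log1p_g = np.logaddexp(0.0, u)
    log1p_g1mr2 = np.logaddexp(0.0, u + math.log1p(-r2)) if r2 < 1 else u
    return (
        0.5 * (n - 1 - p) * log1p_g
        - 0.5 * (n - 1) * log1p_g1mr2
        + log_prior
        + u  # Jacobian dg = g du
    )


def bf_against_null(
    r2: float, n: int, p: int, prior_scale: float = JZS_DEFAULT_SCALE
) -> float:
    """JZS Bayes factor of a p-predictor linear model vs intercept-only.

    Evaluated by adaptive quadrature over u = log g with the integrand
    normalised at its mode.  Raises if the quadrature fails to reach a
    relative accuracy of 1e-6.
    """
    if p == 0:
        return 1.0
    if not 0 <= r2 < 1:
        raise ValueError(f"R^2 must be in [0, 1), got {r2}")
    if n - 1 - p <= 0:
        raise ValueError("model has no residual degrees of freedom")

    def h(u):
        return _log_jzs_integrand(np.asarray(u, dtype=float), n, p, r2, prior_scale)

    opt = optimize.minimize_scalar(
        lambda u: -h(u), bounds=(-40.0, 40.0), method="bounded"
    )
    u0, h0 = float(opt.x), float(h(opt.x))
    val, err = integrate.quad(
        lambda u: math.exp(min(h(u) - h0, 700.0)),
        -np.inf,
        np.inf,
        points=None,
        epsabs=0,
        epsrel=1e-10,
        limit=200,
    )
    if not np.isfinite(val) or val <= 0 or err / val > 1e-6:
        raise RuntimeError(
            f"JZS quadrature failed: value {val}, error estimate {err} "
            f"(n={n}, p={p}, R2={r2}, scale={prior_scale}); "
            f"mode at log g = {u0:.2f}"
        )
    return float(math.exp(h0) * val)


def jzs_bf(
    y,
    X: pd.DataFrame,
    focal: str,
    prior_scale: float = JZS_DEFAULT_SCALE,
) -> float:
    """Effect-level JZS Bayes factor for one predictor in a regression.

    Compares the model with all columns of X to the model omitting the
    focal column, as the ratio of each model's Bayes factor against the
    intercept-only null.  bf10 > 1 is evidence for including the focal
    predictor.
    """
    X = pd.DataFrame(X)
    if focal not in X.columns:
        raise KeyError(f"focal predictor {focal!r} not in design columns")
    ya = np.asarray(y, dtype=float)
    mask = ~np.isnan(ya) & ~np.isnan(X.to_numpy(dtype=float)).any(axis=1)
    ya = ya[mask]
    Xa = X.loc[mask]
    n = ya.size

    def r_squared(cols: list[str]) -> float:
        if not cols:
            return 0.0
        Z = np.column_stack(
            [_zscore(Xa[c].to_numpy(dtype=float)) for c in cols]
        )
        yz = _zscore(ya)
        coef, _, _, _ = np.linalg.lstsq(Z, yz, rcond=None)
        resid = yz - Z @ coef
        return float(1 - (resid @ resid) / (yz @ yz))

    full_cols = list(X.columns)
    reduced_cols = [c for c in full_cols if c != focal]
    bf_full = bf_against_null(r_squared(full_cols), n, len(full_cols), prior_scale)
    bf_reduced = bf_against_null(
        r_squared(reduced_cols), n, len(reduced_cols), prior_scale
    )
    return bf_full / bf_reduced


def power_at_n(n: int, spec: PowerSpec) -> float:
    """Power of the focal-term F test at total sample size n.

    Noncentral F with df1 numerator df, n - n_predictors - 1
    denominator df, and noncentrality lambda = f2 * n.
    """
    df2 = n - spec.n_predictors - 1
    if df2 < 1:
        return 0.0
    fcrit = sps.f.isf(spec.alpha, spec.df1, df2)
    return float(sps.ncf.sf(fcrit, spec.df1, df2, spec.f2 * n))


def required_n(spec: PowerSpec, n_cap: int = 1_000_000) -> int:
    """Smallest total N reaching the target power for the focal term.

    Iterates N upward from the minimal identifiable size; raises if the
    target power is unattainable below ``n_cap``.
    """
    n = spec.n_predictors + 2
    while n <= n_cap:
        if power_at_n(n, spec) >= spec.power:
            return n
        n += 1
    raise ValueError(
        f"power {spec.power} unattainable for f2={spec.f2} below N={n_cap}"
    )
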