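"""Linear and quadratic benchmark regressions.

Ordinary least squares fits of the response on nutrient intake (degree 1)
or intake and intake squared (degree 2), with two-sided t-tests on the
coefficients, the Pearson correlation r, and pointwise t-based confidence
bands for the mean response.  RMSE uses the sqrt(SSE/n) convention so the
values are directly comparable with the tanh-neuron fit RMSEs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import DegenerateDesignError, SampleSizeError, ValidationError


@dataclass
class PolyFit:
    degree: int
    coefficients: np.ndarray       # [intercept, linear(, quadratic)]
    term_p_values: np.ndarray      # aligned with coefficients
    r: float                       # Pearson correlation of x and y
    rmse: float                    # sqrt(SSE/n)
    n: int
    residual_df: int
    sigma2: float                  # unbiased residual variance SSE/(n-p)
    xtx_inv: np.ndarray            # (X'X)^-1 for mean-response bands
    x_min: float
    x_max: float

    def design(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        cols = [np.ones_like(x)] + [x**k for k in range(1, self.degree + 1)]
        return np.column_stack(cols)

    def predict(self, x) -> np.ndarray:
        return self.design(x) @ self.coefficients


def fit_polynomial(x, y, degree: int) -> PolyFit:
    """OLS polynomial fit of degree 1 or 2 with per-term p-values."""
    if degree not in (1, 2):
        raise ValidationError("degree must be 1 or 2")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < degree + 2:
        raise SampleSizeError(f"need >= {degree + 2} points for degree {degree}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant")

    X = np.column_stack([np.ones(n)] + [x**k for k in range(1, degree + 1)])
    res = sm.OLS(y, X).fit()
    sse = float(np.sum(res.resid**2))
    # r as printed alongside the fits: plain Pearson correlation of x and y
    r = float(np.corrcoef(x, y)[0, 1])
    return PolyFit(
        degree=degree,
        coefficients=np.asarray(res.params),
        term_p_values=np.asarray(res.pvalues),
        r=r,
        rmse=float(np.sqrt(sse / n)),
        n=n,
        residual_df=int(res.df_resid),
        sigma2=float(res.mse_resid),
        xtx_inv=np.asarray(res.normalized_cov_params),
        x_min=float(np.min(x)),
        x_max=float(np.max(x)),
    )


def confidence_band(fit: PolyFit, grid, level: float = 0.95):
    """Pointwise t-based confidence band for the mean response.

    Half-width at x0 is t_{df, (1+level)/2} * sqrt(sigma2 * x0'(X'X)^-1 x0).
    Returns (mean, lower, upper, extrapolated) arrays; ``extrapolated``
    marks grid points outside the fitted data range.
    """
    if fit.residual_df <= 0:
        raise SampleSizeError("no residual degrees of freedom for a band")
    grid = np.asarray(grid, dtype=float)
    Xg = fit.design(grid)
    mean = Xg @ fit.coefficients
    se = np.sqrt(fit.sigma2 * np.einsum("ij,jk,ik->i", Xg, fit.xtx_inv, Xg))
    tcrit = stats.t.ppf((1.0 + level) / 2.0, fit.residual_df)
    half = tcrit * se
    extrapolated = (grid < fit.x_min) | (grid > fit.x_max)
    return mean, mean - half, mean + half, extrapolated


@dataclass
class LinearQuadraticSummary:
    rmse_linear: float
    rmse_quadratic: float
    quadratic_term_p: float
    improved: bool
    linear: PolyFit
    quadratic: PolyFit


def compare_linear_quadratic(
    x, y, alpha: float = 0.05
) -> LinearQuadraticSummary:
    """Benchmark comparison: does curvature significantly improve the fit?"""
    lin = fit_polynomial(x, y, 1)
    quad = fit_polynomial(x, y, 2)
    p_quad = float(quad.term_p_values[2])
    return LinearQuadraticSummary(
        rmse_linear=lin.rmse,
        rmse_quadratic=quad.rmse,
        quadratic_term_p=p_quad,
        improved=p_quad < alpha,
        linear=lin,
        quadratic=quad,
    )
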