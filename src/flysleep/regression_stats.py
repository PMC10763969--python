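"""Closed-form OLS slope inference and sequential ANCOVA.

Every regression in the pipeline — reactivity vs time asleep, metabolic
percent change vs time asleep — reduces to a simple line fit with an F-test
on the slope, and genotype comparisons reduce to an analysis of covariance
run sequentially: first test equality of slopes, then (under a common slope)
equality of intercepts.  Both tests are F-ratios of residual sums of squares
of nested linear models:

* separate lines:      y = a_g + b_g x      (2g parameters)
* parallel lines:      y = a_g + b x        (g + 1 parameters)
* single line:         y = a + b x          (2 parameters)

equal slopes:     F = [(RSS_parallel − RSS_separate)/(g−1)] / [RSS_separate/(n−2g)]
equal intercepts: F = [(RSS_single − RSS_parallel)/(g−1)] / [RSS_parallel/(n−g−1)]

Exact fits (zero residual variance) are reported with an ``exact_fit`` flag
instead of dividing by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["RegressionResult", "AncovaResult", "ols_fit", "ancova"]


@dataclass
class RegressionResult:
    """Simple-regression summary with the slope's F-test on (1, n−2) df."""

    n: int
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r2: float
    f_slope: float
    p_slope: float
    exact_fit: bool = False

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        if self.exact_fit:
            return (self.slope, self.slope)
        t = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (self.slope - t * self.se_slope, self.slope + t * self.se_slope)


@dataclass
class AncovaResult:
    """Sequential ANCOVA across g groups sharing one covariate."""

    g: int
    n: int
    f_slopes: float
    df_slopes: tuple[int, int]
    p_slopes: float
    f_intercepts: float
    df_intercepts: tuple[int, int]
    p_intercepts: float
    common_slope: float
    exact_fit: bool = False


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Centered second moments (Sxx, Sxy, Syy) plus the two means."""
    xm, ym = x.mean(), y.mean()
    dx, dy = x - xm, y - ym
    return float(dx @ dx), float(dx @ dy), float(dy @ dy), xm, ym


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line fit with slope standard error, R² and slope F-test.

    Requires n >= 3 observations and non-constant x.  The F statistic is the
    squared slope t with (1, n−2) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx, sxy, syy, xm, ym = _moments(x, y)
    if sxx == 0:
        raise ValueError("x is constant; slope is not identifiable")
    slope = sxy / sxx
    intercept = ym - slope * xm
    rss = max(syy - slope * sxy, 0.0)
    if syy > 0:
        r2 = 1.0 - rss / syy
    else:
        r2 = 1.0  # constant y fitted exactly by the horizontal line
    sigma2 = rss / (n - 2)
    # exact fit: residual variance indistinguishable from zero
    if sigma2 <= 0 or (syy > 0 and rss <= 1e-14 * syy):
        exact = True
        se_slope = 0.0
        se_intercept = 0.0
        f = math.inf if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
        return RegressionResult(n, slope, intercept, se_slope, se_intercept,
                                min(r2, 1.0), f, p, exact)
    se_slope = math.sqrt(sigma2 / sxx)
    se_intercept = math.sqrt(sigma2 * (1.0 / n + xm * xm / sxx))
    f = (slope / se_slope) ** 2
    p = float(stats.f.sf(f, 1, n - 2))
    return RegressionResult(n, slope, intercept, se_slope, se_intercept,
                            max(min(r2, 1.0), 0.0), f, p, False)


def ancova(groups: Sequence[tuple[Sequence[float], Sequence[float]]]) -> AncovaResult:
    """Sequential ANCOVA over ``groups`` = [(x₁, y₁), (x₂, y₂), …].

    Tests equal slopes with df (g−1, n−2g), then equal intercepts under a
    common slope with df (g−1, n−g−1).  Each group must satisfy the
    ``ols_fit`` preconditions.  When a reference model fits exactly the
    corresponding F is reported as ``inf`` (or 0 when the nested model also
    fits exactly) with ``exact_fit`` set.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    g = len(groups)
    xs, ys = [], []
    rss_sep = 0.0
    sxx_sum = sxy_sum = syy_sum = 0.0
    n = 0
    for xg, yg in groups:
        xg = np.asarray(xg, dtype=float)
        yg = np.asarray(yg, dtype=float)
        if xg.ndim != 1 or xg.shape != yg.shape or xg.size < 3:
            raise ValueError("each group needs >= 3 paired observations")
        sxx, sxy, syy, _, _ = _moments(xg, yg)
        if sxx == 0:
            raise ValueError("a group has constant x")
        rss_sep += max(syy - sxy * sxy / sxx, 0.0)
        sxx_sum += sxx
        sxy_sum += sxy
        syy_sum += syy
        n += xg.size
        xs.append(xg)
        ys.append(yg)
    if n <= 2 * g:
        raise ValueError("too few observations for separate-slopes model")
    common_slope = sxy_sum / sxx_sum
    rss_parallel = max(syy_sum - sxy_sum * sxy_sum / sxx_sum, 0.0)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    sxx_a, sxy_a, syy_a, _, _ = _moments(x_all, y_all)
    if sxx_a == 0:
        raise ValueError("pooled x is constant")
    rss_single = max(syy_a - sxy_a * sxy_a / sxx_a, 0.0)

    scale = max(syy_a, 1.0)
    exact = False

    def _f(rss_reduced: float, rss_full: float, df1: int, df2: int) -> tuple[float, float]:
        nonlocal exact
        num = max(rss_reduced - rss_full, 0.0) / df1
        den = rss_full / df2
        if den <= 1e-14 * scale / max(df2, 1):
            exact = True
            if num <= 1e-14 * scale:
                return 0.0, 1.0
            return math.inf, 0.0
        f = num / den
        return f, float(stats.f.sf(f, df1, df2))

    f_slopes, p_slopes = _f(rss_parallel, rss_sep, g - 1, n - 2 * g)
    f_int, p_int = _f(rss_single, rss_parallel, g - 1, n - g - 1)
    return AncovaResult(
        g=g,
        n=n,
        f_slopes=f_slopes,
        df_slopes=(g - 1, n - 2 * g),
        p_slopes=p_slopes,
        f_intercepts=f_int,
        df_intercepts=(g - 1, n - g - 1),
        p_intercepts=p_int,
        common_slope=common_slope,
        exact_fit=exact,
    )
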