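"""Simple (one-predictor) ordinary least squares with an F test.

Shared by the regulatory peak scan and the protein~mRNA regression: both
report slope, R-squared and an F statistic with (1, n-2) degrees of
freedom, whose p-value equals the two-sided slope t-test (t^2 = F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist


@dataclass(frozen=True)
class SimpleOls:
    n: int
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


def simple_ols(x, y) -> SimpleOls:
    """OLS of y on x; F = (n-2) * R^2 / (1 - R^2), p from F(1, n-2).

    A constant response gives slope 0, R^2 = 0, F = 0, p = 1.  A perfect fit
    gives F = inf, p = 0.  Raises for n < 3 or a constant predictor.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("constant predictor: regression is degenerate")
    syy = float(((y - y.mean()) ** 2).sum())
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        r2 = 0.0
    else:
        r2 = sxy * sxy / (sxx * syy)
    df = (1, n - 2)
    if r2 >= 1.0:
        return SimpleOls(n, slope, intercept, 1.0, np.inf, df, 0.0)
    f_stat = (n - 2) * r2 / (1.0 - r2)
    p = float(f_dist.sf(f_stat, *df))
    return SimpleOls(n, slope, intercept, r2, f_stat, df, p)
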