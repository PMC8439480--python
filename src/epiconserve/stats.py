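"""Shared statistical primitives.

Welch's unequal-variances t-test and Pearson correlation are written out from
their defining formulas (the test suite cross-checks them against SciPy);
p-values use SciPy's t distribution. Percentage rounding is half-up to match
how diagnostic tables are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _sps

__all__ = [
    "WelchResult",
    "TrendResult",
    "welch_t_test",
    "pearson",
    "round_percent",
]


@dataclass(frozen=True)
class WelchResult:
    """Two-sided Welch's t-test between two independent samples."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class TrendResult:
    """Pearson correlation used as a trend statistic.

    ``r`` is NaN (and ``defined`` False) when either variable is constant,
    in which case the correlation is undefined rather than zero.
    """

    r: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


def welch_t_test(a, b) -> WelchResult:
    """Welch's unequal-variances t-test, two-sided.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with Welch–Satterthwaite
    degrees of freedom. Requires at least two observations per group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"Welch's t-test needs >=2 observations per group, got {a.size} and {b.size}"
        )
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if ma == mb:
            # identical constant groups: no evidence of a difference
            return WelchResult(0.0, float(na + nb - 2), 1.0, ma, mb, na, nb)
        t = np.inf if ma > mb else -np.inf
        return WelchResult(float(t), float(na + nb - 2), 0.0, ma, mb, na, nb)
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)), float(ma), float(mb), na, nb)


def pearson(x, y) -> TrendResult:
    """Pearson product-moment correlation with a two-sided p-value.

    r = cov(x, y) / (sd(x) sd(y)); p from the exact t transform
    t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom. With fewer than
    three points, or a constant input, r and/or p are reported as NaN
    (undefined), never coerced to zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-d vectors of equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 2:
        return TrendResult(float("nan"), float("nan"), n)
    if (x == x[0]).all() or (y == y[0]).all():
        return TrendResult(float("nan"), float("nan"), n)
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        return TrendResult(float("nan"), float("nan"), n)
    r = float(np.clip(np.sum(dx * dy) / (sx * sy), -1.0, 1.0))
    if n < 3:
        return TrendResult(r, float("nan"), n)
    if abs(r) == 1.0:
        return TrendResult(r, 0.0, n)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return TrendResult(r, float(min(p, 1.0)), n)


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Round ``fraction`` (a proportion) to a percentage, half-up.

    Half-up (0.05 -> 0.1 at one decimal) rather than banker's rounding,
    matching printed diagnostic tables.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))
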