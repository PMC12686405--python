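"""Comparative statistics: urea-N fractions, rank-sum tests, box summaries.

The rank-sum test follows the conventional two-sample
Mann-Whitney-Wilcoxon construction: the W statistic is the rank sum of
the first sample minus its minimum possible value (range 0..n1*n2),
with an exact null distribution when the pooled sample is small and
tie-free, and a tie-corrected, continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

from .errors import ValidationError

#: Largest pooled sample size for which the exact null distribution is used.
EXACT_LIMIT = 20

__all__ = [
    "RankTestResult",
    "BoxSummary",
    "urea_fraction",
    "mann_whitney",
    "box_summary",
    "mean_with_se",
]


@dataclass
class RankTestResult:
    W: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" or "normal_approx_cc"


@dataclass
class BoxSummary:
    n: int
    q25: float
    median: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: list
    whisker_mode: str


def urea_fraction(urea_nM: float, ammonium_nM: float, *,
                  urea_below_lod: bool = False,
                  ammonium_below_lod: bool = False,
                  urea_lod_nM: float | None = None,
                  ammonium_lod_nM: float | None = None,
                  lod_policy: str = "lod") -> float:
    """Fraction of urea-N to combined ammonium-N + urea-N.

    Below-detection values are substituted according to ``lod_policy``:
    "lod" uses the analytical detection limit, "half-lod" uses half of
    it, "zero" uses zero.  Both constituents below detection yields NaN.
    """
    if lod_policy not in ("lod", "half-lod", "zero"):
        raise ValidationError(f"unknown lod_policy {lod_policy!r}")
    if urea_below_lod and ammonium_below_lod:
        return math.nan

    def substitute(value, below, lod):
        if not below:
            if value < 0:
                raise ValidationError("concentrations must be >= 0")
            return value
        if lod_policy == "zero":
            return 0.0
        if lod is None:
            raise ValidationError("below-detection value without an LOD")
        return lod if lod_policy == "lod" else lod / 2.0

    u = substitute(urea_nM, urea_below_lod, urea_lod_nM)
    a = substitute(ammonium_nM, ammonium_below_lod, ammonium_lod_nM)
    total = u + a
    if total == 0:
        return math.nan
    return u / total


@lru_cache(maxsize=None)
def _u_distribution(n1: int, n2: int) -> tuple:
    """Exact null counts of the Mann-Whitney U statistic.

    Classic recurrence: c(u; n1, n2) = c(u - n2; n1-1, n2) + c(u; n1, n2-1).
    Returns a tuple of counts for u = 0..n1*n2.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_distribution(n1 - 1, n2)
    b = _u_distribution(n1, n2 - 1)
    size = n1 * n2 + 1
    counts = [0] * size
    for u in range(size):
        if u - n2 >= 0 and u - n2 < len(a):
            counts[u] += a[u - n2]
        if u < len(b):
            counts[u] += b[u]
    return tuple(counts)


def _exact_p(w: float, n1: int, n2: int, alternative: str) -> float:
    counts = np.array(_u_distribution(n1, n2), dtype=float)
    total = counts.sum()
    w = int(round(w))
    p_le = counts[: w + 1].sum() / total
    p_ge = counts[w:].sum() / total
    if alternative == "less":
        return float(p_le)
    if alternative == "greater":
        return float(p_ge)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two-sided") -> RankTestResult:
    """Two-sample Mann-Whitney-Wilcoxon rank-sum test.

    W is the sum of pooled ranks of ``x`` minus ``n1*(n1+1)/2``.  The p
    value is exact (full null distribution) when the pooled sample has
    no ties and at most ``EXACT_LIMIT`` observations, and otherwise a
    normal approximation with tie and continuity corrections.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")

    pooled = np.concatenate([x, y])
    ranks = _sstats.rankdata(pooled)
    w = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    has_ties = len(np.unique(pooled)) < pooled.size
    if not has_ties and (n1 + n2) <= EXACT_LIMIT:
        return RankTestResult(W=w, p_value=_exact_p(w, n1, n2, alternative),
                              n1=n1, n2=n2, method="exact")

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (n * (n - 1))
    sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term)
    if sigma2 <= 0:
        # all observations identical: no evidence either way
        return RankTestResult(W=w, p_value=1.0, n1=n1, n2=n2,
                              method="normal_approx_cc")
    sigma = math.sqrt(sigma2)
    z = w - mu
    if alternative == "two-sided":
        correction = math.copysign(0.5, z) if z != 0 else 0.0
    elif alternative == "greater":
        correction = 0.5
    else:
        correction = -0.5
    z = (z - correction) / sigma
    if alternative == "less":
        p = _sstats.norm.cdf(z)
    elif alternative == "greater":
        p = _sstats.norm.sf(z)
    else:
        p = min(1.0, 2.0 * min(_sstats.norm.cdf(z), _sstats.norm.sf(z)))
    return RankTestResult(W=w, p_value=float(p), n1=n1, n2=n2,
                          method="normal_approx_cc")


def box_summary(values: Sequence[float],
                whisker_mode: str = "pct10_90") -> BoxSummary:
    """Boxplot summary with one of two whisker conventions.

    Quartiles use linear interpolation (type-7).  ``pct10_90`` places
    whiskers at the 10th and 90th percentiles; ``iqr1_5`` places them
    at the most extreme data points within 1.5x the interquartile range
    of the quartiles.  Points outside the whiskers are listed.
    """
    if whisker_mode not in ("pct10_90", "iqr1_5"):
        raise ValidationError(f"unknown whisker mode {whisker_mode!r}")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValidationError("empty input")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    if whisker_mode == "pct10_90":
        lo, hi = np.percentile(v, [10, 90])
    else:
        iqr = q75 - q25
        inside = v[(v >= q25 - 1.5 * iqr) & (v <= q75 + 1.5 * iqr)]
        lo, hi = float(inside.min()), float(inside.max())
    outliers = sorted(v[(v < lo) | (v > hi)].tolist())
    return BoxSummary(n=int(v.size), q25=float(q25), median=float(med),
                      q75=float(q75), whisker_low=float(lo),
                      whisker_high=float(hi), outliers=outliers,
                      whisker_mode=whisker_mode)


def mean_with_se(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and its standard error (sample SD / sqrt(n))."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 1:
        raise ValidationError("empty input")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
    return mean, se
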