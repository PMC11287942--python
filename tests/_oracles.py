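"""Independent brute-force oracles used by the test suite.

Everything here is written from explicit textbook formulas (sums, normal
equations, enumeration) and never calls the package code it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import distributions, rankdata


def rowwise_day_totals(items, composition_rows):
    """Spreadsheet-style aggregation: per-row amount/100 x per-100 g values."""
    totals: dict[str, float] = {}
    for code, amount in items:
        for col, per100 in composition_rows[code].items():
            totals[col] = totals.get(col, 0.0) + amount / 100.0 * per100
    return totals


def mean_sd(x):
    """Two-pass sample mean and SD with the n-1 denominator."""
    x = list(map(float, x))
    n = len(x)
    m = sum(x) / n
    var = sum((v - m) ** 2 for v in x) / (n - 1)
    return m, math.sqrt(var)


def ols(x, y):
    """Normal-equations simple regression: slope, intercept, r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = (x**2).sum() - x.sum() ** 2 / n
    syy = (y**2).sum() - y.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 0.0
    return slope, intercept, r


def pearson_with_p(x, y):
    """Sigma-formula Pearson r with the exact t-based two-sided p."""
    _, _, r = ols(x, y)
    n = len(x)
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r**2)
    p = 2 * distributions.t.sf(abs(t), n - 2)
    return r, p


def spearman_with_p(x, y):
    """Pearson on mid-ranks, with the same t approximation for p."""
    return pearson_with_p(rankdata(x), rankdata(y))


def paired_t(a, b):
    """t = mean_diff / (sd_diff / sqrt(n)), two-sided p from the t distribution."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    m, s = mean_sd(d)
    t = m / (s / math.sqrt(n))
    return t, 2 * distributions.t.sf(abs(t), n - 1)


def bland_altman_fields(a, b):
    """All agreement fields from explicit formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = a - b
    avg = (a + b) / 2.0
    m, s = mean_sd(d)
    slope, intercept, r = ols(avg, d)
    n = len(d)
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r**2)
    p = 2 * distributions.t.sf(abs(t), n - 2)
    return {
        "mean_diff": m, "sd_diff": s, "loa_lower": m - 2 * s, "loa_upper": m + 2 * s,
        "loa_half_width": 2 * s, "slope": slope, "intercept": intercept, "r": r, "p": p,
    }


def wilcoxon_signed_rank(d, mode: str):
    """Signed-rank statistic and two-sided p.

    ``mode='exact'``: full null distribution of W+ by dynamic programming
    over the rank generating polynomial (no ties assumed).
    ``mode='approx'``: normal approximation without continuity correction.
    """
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if mode == "exact":
        top = int(n * (n + 1) // 2)
        poly = np.zeros(top + 1)
        poly[0] = 1.0
        for r in ranks.astype(int):
            nxt = poly.copy()
            nxt[r:] += poly[: top + 1 - r]
            poly = nxt
        poly /= 2.0**n
        wi = int(round(w))
        p = min(1.0, 2.0 * min(poly[: wi + 1].sum(), poly[wi:].sum()))
    else:
        mu = n * (n + 1) / 4.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        p = 2 * distributions.norm.sf(abs((w - mu) / sigma))
    stat = min(w, n * (n + 1) / 2.0 - w)
    return stat, p
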