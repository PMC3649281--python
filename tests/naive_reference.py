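"""Naive per-gene reference implementations used as independent oracles.

Everything here is written with scalar Python loops, explicit type-7
quantile interpolation and `math` functions, deliberately avoiding the
vectorized code paths (and numpy quantile/median routines) of the package.
"""

from __future__ import annotations

import math

MAD_SCALE = 1.4826


def quantile7(values, p: float) -> float:
    """Linear interpolation of order statistics (R/numpy type 7)."""
    v = sorted(values)
    h = (len(v) - 1) * p
    f = math.floor(h)
    if f + 1 >= len(v):
        return float(v[-1])
    return v[f] + (h - f) * (v[f + 1] - v[f])


def median(values) -> float:
    v = sorted(values)
    n = len(v)
    mid = n // 2
    return float(v[mid]) if n % 2 else 0.5 * (v[mid - 1] + v[mid])


def mad(values, center: float) -> float:
    return MAD_SCALE * median([abs(x - center) for x in values])


def normal_pdf(u: float, mean: float) -> float:
    return math.exp(-0.5 * (u - mean) ** 2) / math.sqrt(2.0 * math.pi)


def t_stat(x, y) -> float:
    n0, n1 = len(x), len(y)
    mx = sum(x) / n0
    my = sum(y) / n1
    vx = sum((a - mx) ** 2 for a in x) / (n0 - 1)
    vy = sum((b - my) ** 2 for b in y) / (n1 - 1)
    sp2 = ((n0 - 1) * vx + (n1 - 1) * vy) / (n0 + n1 - 2)
    se = math.sqrt(sp2 * (1 / n0 + 1 / n1))
    return (my - mx) / se if se > 0 else math.nan


def copa_stat(x, y, r: float) -> float:
    pooled = list(x) + list(y)
    med = median(pooled)
    scale = mad(pooled, med)
    if scale == 0:
        return math.nan
    return (quantile7(y, r / 100.0) - med) / scale


def os_stat(x, y) -> float:
    pooled = list(x) + list(y)
    q75 = quantile7(pooled, 0.75)
    thr = q75 + (q75 - quantile7(pooled, 0.25))
    outliers = [v for v in y if v > thr]
    if not outliers:
        return 0.0
    med = median(pooled)
    scale = mad(pooled, med)
    if scale == 0:
        return math.nan
    return sum((v - med) / scale for v in outliers)


def _mad_star(x, y) -> float:
    med_x, med_y = median(x), median(y)
    dev = [abs(v - med_x) for v in x] + [abs(v - med_y) for v in y]
    return MAD_SCALE * median(dev)


def ort_stat(x, y) -> float:
    q75 = quantile7(x, 0.75)
    thr = q75 + (q75 - quantile7(x, 0.25))
    outliers = [v for v in y if v > thr]
    if not outliers:
        return 0.0
    scale = _mad_star(x, y)
    if scale == 0:
        return math.nan
    med_x = median(x)
    return sum((v - med_x) / scale for v in outliers)


def most_stat(x, y, mu, sigma) -> float:
    scale = _mad_star(x, y)
    if scale == 0:
        return math.nan
    med_x = median(x)
    y_desc = sorted(y, reverse=True)
    best = -math.inf
    csum = 0.0
    for k, v in enumerate(y_desc):
        csum += v - med_x
        best = max(best, (csum / scale - mu[k]) / sigma[k])
    return best


def standardize_gene(x, y):
    n0 = len(x)
    mx = sum(x) / n0
    s = math.sqrt(sum((a - mx) ** 2 for a in x) / (n0 - 1))
    if s == 0:
        return None
    return [(v - mx) / s for v in y]


def posterior_scalar(u: float, pis, means):
    dens = [pis[k] * normal_pdf(u, means[k]) for k in range(3)]
    total = sum(dens)
    return [d / total for d in dens]


def s_stat(u_row, pis, means) -> float:
    prod = 1.0
    for u in u_row:
        prod *= 1.0 - posterior_scalar(u, pis, means)[2]
    return 1.0 - prod


def t_stat_twosided(u_row, pis, means) -> float:
    prod = 1.0
    for u in u_row:
        w = posterior_scalar(u, pis, means)
        prod *= 1.0 - (w[1] + w[2])
    return 1.0 - prod
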