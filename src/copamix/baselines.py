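"""Comparator gene-ranking statistics for cancer outlier detection.

Implements the published one-sided statistics this package benchmarks the
mixture posterior score against:

* two-sample pooled-variance t statistic,
* COPA: a fixed percentile of the cancer samples, centered/scaled by the
  pooled median and MAD,
* OS (outlier sum): sum of standardized cancer exceedances above the pooled
  q75 + IQR threshold,
* ORT: outlier sum with the threshold, center and outlier set defined from
  the normal samples only, and a class-centered pooled MAD,
* MOST: the maximum over all outlier counts k of the standardized
  cumulative sum of the k largest cancer values, normalized by
  Monte-Carlo moments of partial sums of standard-normal order statistics.

Quantiles use linear interpolation of order statistics (numpy's default,
"type 7") and the median of an even count is the mean of the two middle
values; the MAD carries the 1.4826 normality-consistency factor. Statistics
whose scale estimate is zero are returned as NaN and rank last.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io import ExpressionDataset, GeneScoreTable

__all__ = [
    "MAD_SCALE",
    "OrderStatMoments",
    "robust_center_scale_pooled",
    "t_statistic",
    "copa_statistic",
    "os_statistic",
    "ort_statistic",
    "order_statistic_moments",
    "most_statistic",
]

MAD_SCALE = 1.4826  # makes the MAD consistent for the SD under normality

DEFAULT_MOMENT_REPS = 100_000
DEFAULT_MOMENT_SEED = 20130410


def robust_center_scale_pooled(
    dataset: ExpressionDataset, gene: str
) -> tuple[float, float]:
    """Pooled median and scaled MAD of one gene over all n0 + n1 samples."""
    i = dataset.gene_ids.index(gene)
    v = dataset.values[i]
    med = float(np.median(v))
    mad = MAD_SCALE * float(np.median(np.abs(v - med)))
    return med, mad


def _pooled_med_mad(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(values, axis=1)
    mad = MAD_SCALE * np.median(np.abs(values - med[:, None]), axis=1)
    return med, mad


def t_statistic(dataset: ExpressionDataset) -> GeneScoreTable:
    """Two-sample t with the pooled standard error; NaN where it is zero."""
    if dataset.n1 < 2:
        raise ValueError("t statistic needs at least 2 cancer samples")
    x, y = dataset.normal_values, dataset.cancer_values
    n0, n1 = dataset.n0, dataset.n1
    sp2 = ((n0 - 1) * x.var(axis=1, ddof=1) + (n1 - 1) * y.var(axis=1, ddof=1)) / (
        n0 + n1 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (y.mean(axis=1) - x.mean(axis=1)) / se, np.nan)
    return GeneScoreTable(gene_ids=dataset.gene_ids, method="t", score=t)


def copa_statistic(dataset: ExpressionDataset, r: float = 90.0) -> GeneScoreTable:
    """COPA: r-th percentile of cancer samples, robustly centered and scaled."""
    if not 0.0 < r < 100.0:
        raise ValueError("percentile r must lie in (0, 100)")
    med, mad = _pooled_med_mad(dataset.values)
    q = np.quantile(dataset.cancer_values, r / 100.0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        copa = np.where(mad > 0, (q - med) / mad, np.nan)
    return GeneScoreTable(gene_ids=dataset.gene_ids, method="copa", score=copa)


def os_statistic(dataset: ExpressionDataset) -> GeneScoreTable:
    """Outlier sum over cancer values above the pooled q75 + IQR threshold.

    Genes with an empty outlier set score 0; genes with outliers but a zero
    pooled MAD are NaN.
    """
    med, mad = _pooled_med_mad(dataset.values)
    q75 = np.quantile(dataset.values, 0.75, axis=1)
    q25 = np.quantile(dataset.values, 0.25, axis=1)
    thr = q75 + (q75 - q25)
    y = dataset.cancer_values
    outliers = y > thr[:, None]
    any_out = outliers.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(outliers, y - med[:, None], 0.0)
        score = np.where(
            any_out,
            np.where(mad > 0, contrib.sum(axis=1) / mad, np.nan),
            0.0,
        )
    return GeneScoreTable(gene_ids=dataset.gene_ids, method="os", score=score)


def _ort_center_scale_threshold(dataset: ExpressionDataset):
    """Normal-class median/threshold and the class-centered pooled MAD."""
    x, y = dataset.normal_values, dataset.cancer_values
    med_x = np.median(x, axis=1)
    med_y = np.median(y, axis=1)
    q75 = np.quantile(x, 0.75, axis=1)
    q25 = np.quantile(x, 0.25, axis=1)
    thr = q75 + (q75 - q25)
    dev = np.concatenate(
        [np.abs(x - med_x[:, None]), np.abs(y - med_y[:, None])], axis=1
    )
    mad_star = MAD_SCALE * np.median(dev, axis=1)
    return med_x, mad_star, thr


def ort_statistic(dataset: ExpressionDataset) -> GeneScoreTable:
    """Outlier-robust t: outlier sum referenced to the normal samples only."""
    med_x, mad_star, thr = _ort_center_scale_threshold(dataset)
    y = dataset.cancer_values
    outliers = y > thr[:, None]
    any_out = outliers.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(outliers, y - med_x[:, None], 0.0)
        score = np.where(
            any_out,
            np.where(mad_star > 0, contrib.sum(axis=1) / mad_star, np.nan),
            0.0,
        )
    return GeneScoreTable(gene_ids=dataset.gene_ids, method="ort", score=score)


@dataclass(frozen=True)
class OrderStatMoments:
    """Monte-Carlo moments of partial sums of N(0,1) order statistics.

    mu[k-1] and sigma[k-1] are the mean and SD of z_1 + ... + z_k where
    z_1 > z_2 > ... > z_n1 are the descending order statistics of an
    n1-sample from the standard normal.
    """

    n1: int
    mu: np.ndarray
    sigma: np.ndarray
    reps: int
    seed: int


@lru_cache(maxsize=32)
def _order_statistic_moments_cached(n1: int, reps: int, seed: int) -> OrderStatMoments:
    rng = np.random.default_rng(seed)
    # stream in blocks to bound memory for large n1 * reps
    block = max(1, min(reps, int(2e7) // max(n1, 1)))
    count = 0
    s1 = np.zeros(n1)
    s2 = np.zeros(n1)
    while count < reps:
        b = min(block, reps - count)
        z = rng.standard_normal((b, n1))
        z.sort(axis=1)
        csum = np.cumsum(z[:, ::-1], axis=1)
        s1 += csum.sum(axis=0)
        s2 += (csum**2).sum(axis=0)
        count += b
    mu = s1 / reps
    var = (s2 - reps * mu**2) / (reps - 1)
    return OrderStatMoments(
        n1=n1, mu=mu, sigma=np.sqrt(np.maximum(var, 0.0)), reps=reps, seed=seed
    )


def order_statistic_moments(
    n1: int,
    reps: int = DEFAULT_MOMENT_REPS,
    seed: int = DEFAULT_MOMENT_SEED,
) -> OrderStatMoments:
    """Estimate the order-statistic partial-sum moments by simulation.

    Deterministic given (n1, reps, seed) and cached on that key.
    """
    if n1 < 1:
        raise ValueError("n1 must be at least 1")
    if reps < 1000:
        raise ValueError("need at least 1000 Monte-Carlo replicates")
    return _order_statistic_moments_cached(int(n1), int(reps), int(seed))


def most_statistic(
    dataset: ExpressionDataset, moments: OrderStatMoments | None = None
) -> GeneScoreTable:
    """MOST: max over k of the moment-standardized top-k cancer outlier sum.

    Uses ORT's normal-class center and class-centered pooled MAD; NaN when
    that scale is zero.
    """
    if moments is None:
        moments = order_statistic_moments(dataset.n1)
    if moments.n1 != dataset.n1:
        raise ValueError(
            f"moments computed for n1={moments.n1}, dataset has n1={dataset.n1}"
        )
    med_x, mad_star, _ = _ort_center_scale_threshold(dataset)
    y_desc = -np.sort(-dataset.cancer_values, axis=1)
    csum = np.cumsum(y_desc - med_x[:, None], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (csum / mad_star[:, None] - moments.mu) / moments.sigma
        score = np.where(mad_star > 0, z.max(axis=1), np.nan)
    return GeneScoreTable(gene_ids=dataset.gene_ids, method="most", score=score)
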