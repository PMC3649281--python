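"""Reference standardization of cancer-sample expression.

For each gene the cancer-class values are centered by the mean and scaled by
the sample standard deviation (n0 - 1 divisor) of that gene's normal-class
values:

    u_gj = (y_gj - mean_g(x)) / sd_g(x)

Under a no-effect null with shared Gaussian noise the u_gj are approximately
standard normal, which is what the downstream mixture model assumes for its
null component. Genes whose normal-class values are constant (zero scale)
cannot be standardized and are excluded with a warning rather than patched
with a pseudo-count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset

__all__ = ["StandardizedMatrix", "standardize"]

logger = logging.getLogger(__name__)


@dataclass
class StandardizedMatrix:
    """G' x n1 matrix of reference-standardized cancer expression u_gj."""

    gene_ids: list[str]
    u: np.ndarray
    excluded_genes: list[str]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 2 or self.u.shape[0] != len(self.gene_ids):
            raise ValueError("u must be 2-D with one row per retained gene")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("standardized matrix contains non-finite values")

    @property
    def n1(self) -> int:
        return self.u.shape[1]


def standardize(dataset: ExpressionDataset) -> StandardizedMatrix:
    """Standardize cancer samples against the normal-class mean and SD.

    Returns a :class:`StandardizedMatrix`; genes with zero normal-class
    variance are dropped into ``excluded_genes``.
    """
    x = dataset.normal_values
    y = dataset.cancer_values
    xbar = x.mean(axis=1)
    s = x.std(axis=1, ddof=1)
    keep = s > 0.0
    if not np.all(keep):
        excluded = [g for g, k in zip(dataset.gene_ids, keep) if not k]
        logger.warning(
            "excluding %d gene(s) with zero normal-class variance: %s",
            len(excluded),
            excluded[:10],
        )
    else:
        excluded = []
    u = (y[keep] - xbar[keep, None]) / s[keep, None]
    return StandardizedMatrix(
        gene_ids=[g for g, k in zip(dataset.gene_ids, keep) if k],
        u=u,
        excluded_genes=excluded,
    )
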