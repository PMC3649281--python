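"""Three-component normal mixture for standardized cancer expression.

All standardized values u_gj (pooled across genes and cancer samples) are
modeled as a mixture of a null component N(0, 1), an underexpression
component N(delta1, 1) and an overexpression component N(delta2, 1):

    f(u) = pi0 N(u; 0, 1) + pi1 N(u; delta1, 1) + pi2 N(u; delta2, 1)

Component variances are fixed at 1 and the null mean at 0; the free
parameters (pi1, pi2, delta1, delta2) are estimated by EM on the pooled
values, sharing information across both genes and cancer samples. The
posterior probability w_gj,k that observation (g, j) belongs to component k
drives two gene-level selection statistics:

* one-sided  S_g = 1 - prod_j (1 - w_gj,2)   (overexpression outliers)
* two-sided  T_g = 1 - prod_j (1 - w_gj,1 - w_gj,2)

S_g is one minus the posterior probability that no cancer sample of gene g
is an overexpression outlier; genes are selected by largest S_g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from .io import GeneScoreTable
from .standardize import StandardizedMatrix

__all__ = [
    "MixtureParams",
    "EMConfig",
    "MixtureFit",
    "PosteriorArray",
    "log_likelihood",
    "em_fit",
    "posterior",
    "score_overexpression",
    "score_twosided",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Mixing proportions and nonnull component means.

    ``delta1 < delta2`` is enforced for identifiability; a delta may be NaN
    only when its component has (numerically) vanished.
    """

    pi0: float
    pi1: float
    pi2: float
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        pis = np.array([self.pi0, self.pi1, self.pi2], dtype=float)
        if np.any(pis < 0) or np.any(pis > 1):
            raise ValueError("mixing proportions must lie in [0, 1]")
        if abs(pis.sum() - 1.0) > 1e-12:
            raise ValueError("mixing proportions must sum to 1")
        if (
            np.isfinite(self.delta1)
            and np.isfinite(self.delta2)
            and not self.delta1 < self.delta2
        ):
            raise ValueError("require delta1 < delta2")

    @property
    def pi(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1, self.pi2])

    @property
    def means(self) -> np.ndarray:
        return np.array([0.0, self.delta1, self.delta2])


@dataclass(frozen=True)
class EMConfig:
    """EM settings.

    rel_tol
        Convergence threshold on the maximum relative change of the four
        free parameters between iterations (default 1e-4).
    max_iter
        Iteration cap.
    init
        "quantile" (default) starts delta1/delta2 at the 5th/95th
        percentiles of the data clipped to <= -1 / >= +1 with
        pi1 = pi2 = 0.05; alternatively a (pi1, pi2, delta1, delta2) tuple
        or a callable mapping the flat data vector to such a tuple.
    pi_floor
        Lower bound on mixing proportions during iteration, preventing a
        division by zero in the mean update when a component empties.
    """

    rel_tol: float = 1e-4
    max_iter: int = 1000
    init: str | Sequence[float] | Callable[[np.ndarray], Sequence[float]] = "quantile"
    pi_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class MixtureFit:
    """Fitted parameters plus EM diagnostics."""

    params: MixtureParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    config: EMConfig = field(default_factory=EMConfig)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class PosteriorArray:
    """G x n1 x 3 posterior membership probabilities w_gj,k."""

    gene_ids: list[str]
    w: np.ndarray
    cancer_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 3 or self.w.shape[2] != 3:
            raise ValueError("w must have shape (G, n1, 3)")
        if self.w.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match w")
        if np.any(self.w < -1e-12) or np.any(self.w > 1 + 1e-12):
            raise ValueError("posteriors must lie in [0, 1]")
        if np.max(np.abs(self.w.sum(axis=2) - 1.0)) > 1e-9:
            raise ValueError("posterior rows must sum to 1")


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _log_weighted_densities(u: np.ndarray, params: MixtureParams) -> np.ndarray:
    """log(pi_k) + log N(u; mean_k, 1) with shape (..., 3).

    Components with pi_k = 0 (or a NaN mean from a vanished component) get
    log-weight -inf so they contribute exactly nothing.
    """
    u = np.asarray(u, dtype=float)
    means = params.means
    pis = params.pi
    out = np.full(u.shape + (3,), -np.inf)
    for k in range(3):
        if pis[k] > 0 and np.isfinite(means[k]):
            out[..., k] = (
                np.log(pis[k]) - _LOG_SQRT_2PI - 0.5 * (u - means[k]) ** 2
            )
    return out


def log_likelihood(U: StandardizedMatrix | np.ndarray, params: MixtureParams) -> float:
    """Total log-likelihood sum_gj log f(u_gj); overflow-safe via log-sum-exp."""
    u = _as_flat(U)
    if u.size == 0:
        raise ValueError("empty standardized matrix")
    return float(logsumexp(_log_weighted_densities(u, params), axis=-1).sum())


def posterior(
    U: StandardizedMatrix | np.ndarray, params: MixtureParams
) -> PosteriorArray:
    """Component posteriors w_gj,k = pi_k f_k(u_gj) / f(u_gj)."""
    if isinstance(U, StandardizedMatrix):
        u2 = U.u
        gene_ids = U.gene_ids
    else:
        u2 = np.atleast_2d(np.asarray(U, dtype=float))
        gene_ids = [f"g{i + 1}" for i in range(u2.shape[0])]
    w = _posterior_weights(u2, params)
    return PosteriorArray(gene_ids=gene_ids, w=w)


def _posterior_weights(u: np.ndarray, params: MixtureParams) -> np.ndarray:
    a = _log_weighted_densities(u, params)
    a -= a.max(axis=-1, keepdims=True)
    w = np.exp(a)
    w /= w.sum(axis=-1, keepdims=True)
    return w


def _as_flat(U) -> np.ndarray:
    u = U.u if isinstance(U, StandardizedMatrix) else np.asarray(U, dtype=float)
    return np.ravel(u)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _initial_params(u: np.ndarray, config: EMConfig) -> MixtureParams:
    init = config.init
    if callable(init):
        init = init(u)
    if isinstance(init, str):
        if init != "quantile":
            raise ValueError(f"unknown init rule {init!r}")
        d1 = min(float(np.quantile(u, 0.05)), -1.0)
        d2 = max(float(np.quantile(u, 0.95)), 1.0)
        p1 = p2 = 0.05
    else:
        p1, p2, d1, d2 = (float(v) for v in init)
    return MixtureParams(
        pi0=1.0 - p1 - p2, pi1=p1, pi2=p2, delta1=d1, delta2=d2
    )


def em_fit(
    U: StandardizedMatrix | np.ndarray, config: EMConfig | None = None
) -> MixtureFit:
    """Fit the three-component mixture by EM on the pooled values.

    E-step: posterior weights from the current parameters. M-step:
    pi_k = mean weight of component k; delta_k = weighted mean of u for
    k in {1, 2} (the null mean stays 0, all variances stay 1). After each
    M-step components 1 and 2 are relabeled if needed so delta1 < delta2.
    Iteration stops when the maximum relative change of the four free
    parameters drops below ``rel_tol``.
    """
    config = config or EMConfig()
    u = _as_flat(U)
    if u.size == 0:
        raise ValueError("empty standardized matrix")
    if np.unique(u).size < 3:
        raise ValueError("need at least 3 distinct standardized values")

    params = _initial_params(u, config)
    trace: list[float] = []
    converged = False
    n_iter = 0
    a = np.empty((u.size, 3))
    for n_iter in range(1, config.max_iter + 1):
        # E-step, written out for speed on ~10^6 pooled values
        means = params.means
        logpi = np.log(params.pi)
        for k in range(3):
            np.subtract(u, means[k], out=a[:, k])
            np.square(a[:, k], out=a[:, k])
            a[:, k] *= -0.5
            a[:, k] += logpi[k]
        amax = a.max(axis=1)
        w = np.exp(a - amax[:, None])
        norm = w.sum(axis=1)
        loglik = float((amax + np.log(norm)).sum()) - u.size * _LOG_SQRT_2PI
        trace.append(loglik)
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite mixture likelihood")
        w /= norm[:, None]

        wsum = w.sum(axis=0)
        pi = wsum / u.size
        pi = np.maximum(pi, config.pi_floor)
        pi /= pi.sum()
        d1 = float(w[:, 1] @ u / max(wsum[1], config.pi_floor * u.size))
        d2 = float(w[:, 2] @ u / max(wsum[2], config.pi_floor * u.size))
        if d1 > d2:  # relabel to keep delta1 < delta2
            d1, d2 = d2, d1
            pi = pi[[0, 2, 1]]
        elif d1 == d2:
            d2 = np.nextafter(d2, np.inf)
        new = MixtureParams(
            pi0=float(1.0 - pi[1] - pi[2]),
            pi1=float(pi[1]),
            pi2=float(pi[2]),
            delta1=d1,
            delta2=d2,
        )
        old_free = np.array(
            [params.pi1, params.pi2, params.delta1, params.delta2]
        )
        new_free = np.array([new.pi1, new.pi2, new.delta1, new.delta2])
        rel = np.abs(new_free - old_free) / np.maximum(np.abs(old_free), 1e-8)
        params = new
        if np.max(rel) < config.rel_tol:
            converged = True
            break

    trace.append(log_likelihood(u, params))
    params = _flag_empty_components(params, config)
    return MixtureFit(
        params=params,
        loglik_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        config=config,
    )


def _flag_empty_components(params: MixtureParams, config: EMConfig) -> MixtureParams:
    """Report a vanished component (pi within 10x of the floor) with a NaN mean."""
    at_floor1 = params.pi1 <= config.pi_floor * 10
    at_floor2 = params.pi2 <= config.pi_floor * 10
    if at_floor1 or at_floor2:
        which = [n for n, f in (("under", at_floor1), ("over", at_floor2)) if f]
        warnings.warn(
            f"mixture component(s) {which} vanished (pi at floor); "
            "their means are reported as NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        params = replace(
            params,
            delta1=np.nan if at_floor1 else params.delta1,
            delta2=np.nan if at_floor2 else params.delta2,
        )
    return params


# ---------------------------------------------------------------------------
# gene-level selection statistics
# ---------------------------------------------------------------------------

def score_overexpression(W: PosteriorArray) -> GeneScoreTable:
    """S_g = 1 - prod_j (1 - w_gj,2), accumulated in log space.

    One minus the posterior probability that no cancer sample of the gene
    is an overexpression outlier.
    """
    with np.errstate(divide="ignore"):  # log1p(-1) = -inf is the saturated case
        s = -np.expm1(np.sum(np.log1p(-np.minimum(W.w[:, :, 2], 1.0)), axis=1))
    return GeneScoreTable(gene_ids=W.gene_ids, method="S", score=np.clip(s, 0.0, 1.0))


def score_twosided(W: PosteriorArray) -> GeneScoreTable:
    """T_g = 1 - prod_j (1 - w_gj,1 - w_gj,2); T_g >= S_g always."""
    wnn = np.minimum(W.w[:, :, 1] + W.w[:, :, 2], 1.0)
    with np.errstate(divide="ignore"):
        t = -np.expm1(np.sum(np.log1p(-wnn), axis=1))
    return GeneScoreTable(gene_ids=W.gene_ids, method="T", score=np.clip(t, 0.0, 1.0))
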