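"""Scikit-learn style estimators over the gene-ranking statistics.

Each scorer follows the (n_samples, n_genes) orientation: rows are
biological samples, columns are genes, and ``y`` holds the two-class sample
labels. After ``fit`` the per-gene statistic is available as ``scores_``
(NaN where undefined), and with ``k`` set the estimator acts as a feature
selector keeping the k top-ranked genes, so it composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import baselines, mixture
from .io import ExpressionDataset, rank_scores
from .standardize import standardize

__all__ = [
    "TTestScorer",
    "CopaScorer",
    "OutlierSumScorer",
    "OutlierRobustTScorer",
    "MaxOrderedSumScorer",
    "MixtureOutlierScorer",
]


class _BaseGeneScorer(SelectorMixin, BaseEstimator):
    """Shared fit plumbing: label handling, dataset assembly, top-k support."""

    def __init__(self, k=None, reference=None):
        self.k = k
        self.reference = reference

    def _resolve_reference(self, y) -> str:
        levels = np.unique(np.asarray(y).astype(str))
        if len(levels) != 2:
            raise ValueError(
                f"y must have exactly two classes, got {levels.tolist()}"
            )
        if self.reference is not None:
            if str(self.reference) not in levels:
                raise ValueError(
                    f"reference={self.reference!r} not among classes {levels.tolist()}"
                )
            return str(self.reference)
        if set(levels) <= {"0", "1", "False", "True"}:
            return sorted(levels)[0]  # 0/False is the normal class
        raise ValueError(
            "pass reference=<normal-class label> for non-binary label encodings"
        )

    def _dataset(self, X, y) -> ExpressionDataset:
        X = check_array(X, dtype=float, ensure_min_samples=3)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent numbers of samples")
        ref = self._resolve_reference(y)
        self.n_features_in_ = X.shape[1]
        self.reference_ = ref
        return ExpressionDataset(
            gene_ids=[f"g{j + 1}" for j in range(X.shape[1])],
            values=X.T,
            labels=y.astype(str),
            reference=ref,
        )

    def fit(self, X, y):
        dataset = self._dataset(X, y)
        self.scores_ = self._score_dataset(dataset)
        return self

    def _score_dataset(self, dataset: ExpressionDataset) -> np.ndarray:
        raise NotImplementedError

    def _get_support_mask(self):
        check_is_fitted(self, "scores_")
        if self.k is None:
            return np.ones(self.n_features_in_, dtype=bool)
        if not 1 <= int(self.k) <= self.n_features_in_:
            raise ValueError(f"k must be in [1, {self.n_features_in_}]")
        return rank_scores(self.scores_) <= int(self.k)


class TTestScorer(_BaseGeneScorer):
    """Two-sample pooled-variance t statistic per gene."""

    def _score_dataset(self, dataset):
        return baselines.t_statistic(dataset).score


class CopaScorer(_BaseGeneScorer):
    """COPA: r-th cancer percentile, centered/scaled by pooled median/MAD."""

    def __init__(self, k=None, reference=None, r=90.0):
        super().__init__(k=k, reference=reference)
        self.r = r

    def _score_dataset(self, dataset):
        return baselines.copa_statistic(dataset, r=self.r).score


class OutlierSumScorer(_BaseGeneScorer):
    """Outlier sum above the pooled q75 + IQR threshold."""

    def _score_dataset(self, dataset):
        return baselines.os_statistic(dataset).score


class OutlierRobustTScorer(_BaseGeneScorer):
    """Outlier-robust t: outlier sum referenced to the normal class only."""

    def _score_dataset(self, dataset):
        return baselines.ort_statistic(dataset).score


class MaxOrderedSumScorer(_BaseGeneScorer):
    """MOST: max standardized cumulative sum over ordered cancer values."""

    def __init__(
        self,
        k=None,
        reference=None,
        reps=baselines.DEFAULT_MOMENT_REPS,
        seed=baselines.DEFAULT_MOMENT_SEED,
    ):
        super().__init__(k=k, reference=reference)
        self.reps = reps
        self.seed = seed

    def _score_dataset(self, dataset):
        moments = baselines.order_statistic_moments(dataset.n1, self.reps, self.seed)
        return baselines.most_statistic(dataset, moments).score


class MixtureOutlierScorer(_BaseGeneScorer):
    """Gene scores from the three-component mixture fit on standardized data.

    Fits N(0,1) + N(delta1,1) + N(delta2,1) by EM to all standardized
    cancer values pooled across genes, then scores genes by the posterior
    outlier statistic: ``method="S"`` (one-sided overexpression, default)
    or ``method="T"`` (two-sided).

    Attributes
    ----------
    pi_ : ndarray of shape (3,)
        Fitted mixing proportions (null, under, over).
    delta_ : ndarray of shape (2,)
        Fitted nonnull component means (NaN if a component vanished).
    posterior_ : ndarray of shape (n_genes, n_cancer, 3)
        Component posteriors per gene and cancer sample (NaN rows for genes
        excluded by zero normal-class variance).
    scores_ : ndarray of shape (n_genes,)
        S_g or T_g per gene.
    """

    def __init__(
        self,
        k=None,
        reference=None,
        method="S",
        rel_tol=1e-4,
        max_iter=1000,
        init="quantile",
        pi_floor=1e-10,
    ):
        super().__init__(k=k, reference=reference)
        self.method = method
        self.rel_tol = rel_tol
        self.max_iter = max_iter
        self.init = init
        self.pi_floor = pi_floor

    def _score_dataset(self, dataset):
        if self.method not in ("S", "T"):
            raise ValueError("method must be 'S' or 'T'")
        U = standardize(dataset)
        config = mixture.EMConfig(
            rel_tol=self.rel_tol,
            max_iter=self.max_iter,
            init=self.init,
            pi_floor=self.pi_floor,
        )
        fit = mixture.em_fit(U, config)
        W = mixture.posterior(U, fit.params)
        self.pi_ = fit.params.pi
        self.delta_ = np.array([fit.params.delta1, fit.params.delta2])
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.loglik_trace_ = fit.loglik_trace
        self.excluded_genes_ = list(U.excluded_genes)

        table = (
            mixture.score_overexpression(W)
            if self.method == "S"
            else mixture.score_twosided(W)
        )
        # scatter back to the full gene set; excluded genes stay NaN
        idx = {g: i for i, g in enumerate(dataset.gene_ids)}
        scores = np.full(dataset.n_genes, np.nan)
        post = np.full((dataset.n_genes, dataset.n1, 3), np.nan)
        for j, g in enumerate(U.gene_ids):
            scores[idx[g]] = table.score[j]
            post[idx[g]] = W.w[j]
        self.posterior_ = post
        return scores
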