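"""Dataset containers and tab-delimited input/output.

The expression matrix convention throughout the package is genes x samples
(G x n), with a two-level sample label vector distinguishing the reference
(normal) class from the cancer class. All file formats are plain
tab-delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneScoreTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_gene_scores",
    "write_posteriors",
    "rank_scores",
]

#: Score methods a GeneScoreTable may carry.
VALID_METHODS = ("t", "copa", "os", "ort", "most", "S", "T")


@dataclass
class ExpressionDataset:
    """A genes x samples matrix of log-scale expression with two-class labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, length G.
    values
        G x n real matrix of normalized log-scale expression.
    labels
        Length-n class label per sample; exactly two distinct levels.
    reference
        The label level of the reference (normal) class. The other level is
        the cancer class.
    sample_ids
        Optional sample names, length n; defaults to s1..sn.
    """

    gene_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    reference: str
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        G, n = self.values.shape
        if G < 1:
            raise ValueError("dataset must contain at least one gene")
        if len(self.gene_ids) != G:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(set(self.gene_ids)) != G:
            raise ValueError("duplicate gene identifier")
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match matrix columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        levels = set(str(l) for l in self.labels)
        if len(levels) != 2:
            raise ValueError(
                f"labels must have exactly two levels, got {sorted(levels)}"
            )
        if str(self.reference) not in levels:
            raise ValueError(f"reference label {self.reference!r} not found in labels")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix columns")
        if self.n0 < 2:
            raise ValueError(
                "need at least 2 reference samples to estimate the normal-class scale"
            )
        if self.n1 < 1:
            raise ValueError("need at least 1 cancer sample")

    # -- derived views -----------------------------------------------------

    @property
    def normal_mask(self) -> np.ndarray:
        return np.asarray([str(l) == str(self.reference) for l in self.labels])

    @property
    def cancer_label(self) -> str:
        levels = {str(l) for l in self.labels}
        (other,) = levels - {str(self.reference)}
        return other

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n0(self) -> int:
        return int(self.normal_mask.sum())

    @property
    def n1(self) -> int:
        return int((~self.normal_mask).sum())

    @property
    def normal_values(self) -> np.ndarray:
        """G x n0 submatrix of the reference class."""
        return self.values[:, self.normal_mask]

    @property
    def cancer_values(self) -> np.ndarray:
        """G x n1 submatrix of the cancer class, in original column order."""
        return self.values[:, ~self.normal_mask]

    @property
    def cancer_sample_ids(self) -> list[str]:
        mask = ~self.normal_mask
        return [s for s, m in zip(self.sample_ids, mask) if m]


@dataclass
class GeneScoreTable:
    """Per-gene values of one ranking statistic.

    ``score`` may contain NaN where the statistic is undefined (e.g. a zero
    scale estimate); NaN scores rank last.
    """

    gene_ids: list[str]
    method: str
    score: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.method not in VALID_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.score.shape != (len(self.gene_ids),):
            raise ValueError("score length does not match gene_ids")

    def ranks(self) -> np.ndarray:
        """1-based ranks: descending score, NaN last, ties by input order."""
        return rank_scores(self.score)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "method": self.method,
                "score": self.score,
                "rank": self.ranks(),
            }
        )


def rank_scores(score: np.ndarray) -> np.ndarray:
    """Rank 1 = largest; NaN ranks last; ties broken by input order."""
    score = np.asarray(score, dtype=float)
    # stable argsort of the negated scores keeps ties in input order and
    # pushes NaN to the end (NaN sorts last in numpy)
    order = np.argsort(-score, kind="stable")
    ranks = np.empty(len(score), dtype=int)
    ranks[order] = np.arange(1, len(score) + 1)
    return ranks


def score_order(score: np.ndarray) -> np.ndarray:
    """Gene indices from best to worst under the ranking rule above."""
    return np.argsort(-np.asarray(score, dtype=float), kind="stable")


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_expression_matrix(
    matrix_path: str | Path,
    labels_path: str | Path,
    reference_label: str,
) -> ExpressionDataset:
    """Read a tab-delimited expression matrix plus a sample-label file.

    The matrix file has a header row of sample names and gene ids in the
    first column. The labels file is two tab-delimited columns
    (sample name, class label) with no header. Every sample column must
    appear in the labels file; column order of the matrix is preserved.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        raise ValueError("duplicate gene identifier in matrix file")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains missing or non-finite values")

    lab = pd.read_csv(labels_path, sep="\t", header=None, dtype=str)
    if lab.shape[1] != 2:
        raise ValueError("labels file must have exactly two tab-delimited columns")
    mapping = dict(zip(lab[0], lab[1]))
    missing = [c for c in df.columns if c not in mapping]
    if missing:
        raise ValueError(f"samples absent from labels file: {missing}")
    labels = np.asarray([mapping[c] for c in df.columns])
    return ExpressionDataset(
        gene_ids=list(df.index),
        values=values,
        labels=labels,
        reference=str(reference_label),
        sample_ids=list(df.columns),
    )


def write_expression_matrix(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
) -> None:
    """Write a dataset back to the matrix + labels file pair (12 sig. digits)."""
    df = pd.DataFrame(
        dataset.values, index=dataset.gene_ids, columns=dataset.sample_ids
    )
    df.index.name = "gene_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.12g")
    with open(labels_path, "w") as fh:
        for s, l in zip(dataset.sample_ids, dataset.labels):
            fh.write(f"{s}\t{l}\n")


def write_gene_scores(table: GeneScoreTable, path: str | Path) -> None:
    """Write gene_id / method / score / rank as tab-delimited text.

    Undefined scores are written as ``NA`` and carry the last ranks.
    """
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def write_posteriors(posteriors, gene_subset: list[str], path: str | Path) -> None:
    """Write component posteriors for selected genes in long format.

    One row per (gene, cancer sample) with columns gene_id, cancer_sample,
    w0, w1, w2. Raises on unknown gene ids.
    """
    index = {g: i for i, g in enumerate(posteriors.gene_ids)}
    unknown = [g for g in gene_subset if g not in index]
    if unknown:
        raise KeyError(f"unknown gene id(s): {unknown}")
    sample_ids = posteriors.cancer_sample_ids
    rows = []
    for g in gene_subset:
        w = posteriors.w[index[g]]  # n1 x 3
        for j in range(w.shape[0]):
            sid = sample_ids[j] if sample_ids else f"c{j + 1}"
            rows.append((g, sid, w[j, 0], w[j, 1], w[j, 2]))
    df = pd.DataFrame(rows, columns=["gene_id", "cancer_sample", "w0", "w1", "w2"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
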