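"""Synthetic outlier-expression datasets with known truth, and FDR/TPR evaluation.

The generator emulates a two-class microarray study: G genes by n samples
(first half normal, second half cancer), base noise drawn i.i.d. per entry
from N(0,1) or a central t with 20 degrees of freedom (used unscaled), no
correlation across genes. Genes split into null / underexpressed /
overexpressed components with proportions pi_gene (default 0.6/0.2/0.2).
For each nonnull gene a random subset of round(phi * n1) cancer samples —
the cancer outliers — receives an additive shift of delta1 (under, default
-2) or delta2 (over, default +2).

Rankings are evaluated by false discovery rate and true positive rate over
the top-m gene lists, with the overexpressed genes as the target set; the
TPR denominator is the full target count (G * pi_over), so TPR is average
power. Experiments average FDR and TPR across replicates at each fixed m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines, mixture
from .io import ExpressionDataset, GeneScoreTable, score_order
from .standardize import standardize

__all__ = [
    "SimConfig",
    "SimTruth",
    "FdrTprCurve",
    "ExperimentResult",
    "generate_dataset",
    "evaluate_ranking",
    "run_experiment",
    "plot_curves",
]

COMPONENTS = ("null", "under", "over")


@dataclass(frozen=True)
class SimConfig:
    """Study design for the synthetic generator.

    n is the total sample count, split evenly into normal and cancer
    classes; phi is the proportion of cancer samples that are outliers for
    each nonnull gene.
    """

    G: int = 10_000
    n: int = 200
    phi: float = 0.5
    pi_gene: tuple[float, float, float] = (0.6, 0.2, 0.2)
    delta1: float = -2.0
    delta2: float = 2.0
    noise: str = "normal"
    n_reps: int = 200
    seed: int = 0
    outlier_sampling: str = "fixed"  # "fixed" count or per-sample "bernoulli"

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be at least 1")
        if self.n < 4 or self.n % 2:
            raise ValueError("n must be even (n0 = n1 = n/2) and at least 4")
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("phi must lie in (0, 1]")
        if abs(sum(self.pi_gene) - 1.0) > 1e-12 or any(p < 0 for p in self.pi_gene):
            raise ValueError("pi_gene must be nonnegative and sum to 1")
        if self.noise not in ("normal", "t20"):
            raise ValueError("noise must be 'normal' or 't20'")
        if self.outlier_sampling not in ("fixed", "bernoulli"):
            raise ValueError("outlier_sampling must be 'fixed' or 'bernoulli'")

    @property
    def n1(self) -> int:
        return self.n // 2

    @property
    def outliers_per_gene(self) -> int:
        return int(round(self.phi * self.n1))


@dataclass
class SimTruth:
    """Ground truth: per-gene component labels and the outlier observations."""

    gene_component: np.ndarray  # length G, values in COMPONENTS
    outlier_mask: np.ndarray  # G x n1 boolean

    def target_genes(self, target: str = "over") -> np.ndarray:
        if target not in COMPONENTS:
            raise ValueError(f"unknown component {target!r}")
        return np.asarray(self.gene_component) == target


@dataclass
class FdrTprCurve:
    """FDR and TPR over top-m selections, m = 1..G."""

    n_selected: np.ndarray
    fdr: np.ndarray
    tpr: np.ndarray

    def tpr_at_fdr(self, fdr_level: float) -> float:
        """TPR at the list size whose (mean) FDR is closest to fdr_level."""
        m = int(np.argmin(np.abs(self.fdr - fdr_level)))
        return float(self.tpr[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_selected": self.n_selected, "fdr": self.fdr, "tpr": self.tpr}
        )


def generate_dataset(
    config: SimConfig, rep_seed: int = 0
) -> tuple[ExpressionDataset, SimTruth]:
    """Draw one synthetic dataset; reproducible from (config.seed, rep_seed).

    Gene components are assigned deterministically: the first
    round(G*pi0) genes are null, the next round(G*pi1) underexpressed, the
    rest overexpressed (entries are i.i.d., so order carries no information).
    """
    rng = np.random.default_rng([int(config.seed), int(rep_seed)])
    G, n, n1 = config.G, config.n, config.n1
    n0 = n - n1

    n_null = int(round(G * config.pi_gene[0]))
    n_under = int(round(G * config.pi_gene[1]))
    n_over = G - n_null - n_under
    component = np.repeat(COMPONENTS, [n_null, n_under, n_over])

    if config.noise == "normal":
        values = rng.standard_normal((G, n))
    else:
        values = rng.standard_t(20, size=(G, n))

    nonnull = component != "null"
    n_nonnull = int(nonnull.sum())
    outlier_mask = np.zeros((G, n1), dtype=bool)
    if n_nonnull:
        if config.outlier_sampling == "fixed":
            k = config.outliers_per_gene
            if k == 0:
                raise ValueError(
                    f"round(phi * n1) = 0 for phi={config.phi}, n1={n1}: "
                    "no outlier samples representable"
                )
            # uniformly random k-subset per nonnull gene
            pick = np.argsort(rng.random((n_nonnull, n1)), axis=1)[:, :k]
            sub = np.zeros((n_nonnull, n1), dtype=bool)
            np.put_along_axis(sub, pick, True, axis=1)
        else:
            sub = rng.random((n_nonnull, n1)) < config.phi
        outlier_mask[nonnull] = sub

    shift = np.where(component == "under", config.delta1, config.delta2)
    values[:, n0:] += outlier_mask * shift[:, None]

    dataset = ExpressionDataset(
        gene_ids=[f"g{i + 1}" for i in range(G)],
        values=values,
        labels=np.asarray(["normal"] * n0 + ["cancer"] * n1),
        reference="normal",
        sample_ids=[f"s{i + 1}" for i in range(n)],
    )
    return dataset, SimTruth(gene_component=component, outlier_mask=outlier_mask)


def evaluate_ranking(
    scores: GeneScoreTable, truth: SimTruth, target: str = "over"
) -> FdrTprCurve:
    """FDR/TPR over top-m lists for a ranking against the known truth.

    Genes are ordered by descending score, NaN last, ties by gene order.
    """
    is_target = truth.target_genes(target)
    if len(is_target) != len(scores.gene_ids):
        raise ValueError("scores and truth have different gene counts")
    order = score_order(scores.score)
    hits = np.cumsum(is_target[order])
    m = np.arange(1, len(order) + 1)
    n_target = int(is_target.sum())
    if n_target == 0:
        raise ValueError(f"truth contains no {target!r} genes")
    return FdrTprCurve(n_selected=m, fdr=(m - hits) / m, tpr=hits / n_target)


# ---------------------------------------------------------------------------
# the full experiment
# ---------------------------------------------------------------------------

def _mixture_scores(
    dataset: ExpressionDataset, methods: Sequence[str], em_config
) -> dict[str, GeneScoreTable]:
    """Fit the mixture once and emit whichever of S/T were requested."""
    U = standardize(dataset)
    fit = mixture.em_fit(U, em_config)
    W = mixture.posterior(U, fit.params)
    out: dict[str, GeneScoreTable] = {}
    retained = {g: i for i, g in enumerate(U.gene_ids)}

    def full_length(table: GeneScoreTable, method: str) -> GeneScoreTable:
        # excluded zero-variance genes come back as NaN so gene order is kept
        score = np.full(dataset.n_genes, np.nan)
        for i, g in enumerate(dataset.gene_ids):
            j = retained.get(g)
            if j is not None:
                score[i] = table.score[j]
        return GeneScoreTable(dataset.gene_ids, method, score)

    if "S" in methods:
        out["S"] = full_length(mixture.score_overexpression(W), "S")
    if "T" in methods:
        out["T"] = full_length(mixture.score_twosided(W), "T")
    return out


def compute_scores(
    dataset: ExpressionDataset,
    methods: Sequence[str],
    copa_r: float = 90.0,
    most_moments: baselines.OrderStatMoments | None = None,
    em_config: mixture.EMConfig | None = None,
) -> dict[str, GeneScoreTable]:
    """Compute any subset of the six ranking statistics on one dataset."""
    out: dict[str, GeneScoreTable] = {}
    simple: Mapping[str, Callable[[ExpressionDataset], GeneScoreTable]] = {
        "t": baselines.t_statistic,
        "copa": lambda d: baselines.copa_statistic(d, r=copa_r),
        "os": baselines.os_statistic,
        "ort": baselines.ort_statistic,
        "most": lambda d: baselines.most_statistic(d, most_moments),
    }
    unknown = [m for m in methods if m not in (*simple, "S", "T")]
    if unknown:
        raise ValueError(f"unknown method(s): {unknown}")
    for name, fn in simple.items():
        if name in methods:
            out[name] = fn(dataset)
    if "S" in methods or "T" in methods:
        out.update(_mixture_scores(dataset, methods, em_config))
    return out


@dataclass
class ExperimentResult:
    """Replicate-averaged FDR/TPR curves per method."""

    config: SimConfig
    curves: dict[str, FdrTprCurve] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for method, curve in self.curves.items():
            df = curve.to_frame()
            df.insert(0, "method", method)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def tpr_at_fdr(self, fdr_level: float = 0.1) -> dict[str, float]:
        return {m: c.tpr_at_fdr(fdr_level) for m, c in self.curves.items()}


def run_experiment(
    config: SimConfig,
    methods: Sequence[str] = ("t", "copa", "os", "ort", "most", "S"),
    copa_r: float = 90.0,
    most_reps: int = baselines.DEFAULT_MOMENT_REPS,
    most_seed: int = baselines.DEFAULT_MOMENT_SEED,
    em_config: mixture.EMConfig | None = None,
    target: str = "over",
) -> ExperimentResult:
    """Generate config.n_reps datasets, score each, and average the curves.

    FDR and TPR are averaged across replicates at each fixed list size m.
    """
    moments = (
        baselines.order_statistic_moments(config.n1, most_reps, most_seed)
        if "most" in methods
        else None
    )
    sum_fdr = {m: np.zeros(config.G) for m in methods}
    sum_tpr = {m: np.zeros(config.G) for m in methods}
    for rep in range(config.n_reps):
        dataset, truth = generate_dataset(config, rep_seed=rep)
        tables = compute_scores(
            dataset, methods, copa_r=copa_r, most_moments=moments, em_config=em_config
        )
        for m in methods:
            curve = evaluate_ranking(tables[m], truth, target=target)
            sum_fdr[m] += curve.fdr
            sum_tpr[m] += curve.tpr
    n_sel = np.arange(1, config.G + 1)
    curves = {
        m: FdrTprCurve(
            n_selected=n_sel,
            fdr=sum_fdr[m] / config.n_reps,
            tpr=sum_tpr[m] / config.n_reps,
        )
        for m in methods
    }
    return ExperimentResult(config=config, curves=curves)


def plot_curves(result_frame: pd.DataFrame, path: str, title: str = "") -> None:
    """Render TPR-vs-FDR ROC curves (one line per method) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for method, grp in result_frame.groupby("method"):
        grp = grp.sort_values("n_selected")
        ax.plot(grp["fdr"], grp["tpr"], label=str(method))
    ax.set_xlabel("FDR")
    ax.set_ylabel("TPR")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
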