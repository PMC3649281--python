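import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from copamix import ExpressionDataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(x: np.ndarray, y: np.ndarray, gene_ids=None) -> ExpressionDataset:
    """Assemble a dataset from normal-class (G x n0) and cancer (G x n1) blocks."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    G = x.shape[0]
    return ExpressionDataset(
        gene_ids=gene_ids or [f"g{i + 1}" for i in range(G)],
        values=np.hstack([x, y]),
        labels=np.asarray(["N"] * x.shape[1] + ["C"] * y.shape[1]),
        reference="N",
    )


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """3 genes x (2 normal + 3 cancer) with one obvious outlier gene."""
    x = np.array([[0.0, 2.0], [1.0, 3.0], [5.0, 6.0]])
    y = np.array([[3.0, 0.5, 1.5], [2.0, 2.5, 9.0], [5.5, 5.2, 5.8]])
    return make_dataset(x, y)


def random_dataset(rng: np.random.Generator, G=8, n0=6, n1=5) -> ExpressionDataset:
    x = rng.normal(size=(G, n0))
    y = rng.normal(size=(G, n1))
    # give some genes a shifted cancer subset so outlier sets are nonempty
    shift_genes = rng.random(G) < 0.5
    y[shift_genes, : max(1, n1 // 2)] += 3.0
    return make_dataset(x, y)
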