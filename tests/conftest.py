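import numpy as np
import pytest

from kldnet import (
    ExpressionMatrix,
    LabelledDataset,
    SampleLabels,
    SimulationConfig,
    simulate,
)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with distinct values."""
    values = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],
            [10.0, 11.5, 12.0, 13.0],
            [100.0, 90.0, 80.0, 70.0],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def tiny_matrix_tsv(tmp_path, tiny_matrix):
    path = tmp_path / "matrix.tsv"
    lines = ["gene_id\t" + "\t".join(tiny_matrix.sample_ids)]
    for g, row in zip(tiny_matrix.gene_ids, tiny_matrix.values):
        lines.append(g + "\t" + "\t".join(f"{v:g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def make_labelled(values: np.ndarray, y: np.ndarray) -> LabelledDataset:
    """Build a LabelledDataset from raw arrays with generated ids."""
    n_genes, n_samples = values.shape
    gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    return LabelledDataset(
        ExpressionMatrix(gene_ids, sample_ids, values),
        SampleLabels(sample_ids, y),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-signal dataset shared across tests: 200 genes,
    60 tumor / 12 normal, 10 planted at LFC 2."""
    cfg = SimulationConfig(
        n_genes=200, n_tumor=60, n_normal=12, n_differential=10, seed=1
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def separable_toy():
    """20 samples, 2 features, linearly separable by feature 0."""
    rng = np.random.default_rng(42)
    n = 20
    y = np.array([1] * 10 + [0] * 10)
    x0 = np.where(y == 1, 100.0, 5.0) + rng.uniform(0, 2, n)
    x1 = rng.uniform(0, 50, n)
    values = np.vstack([x0, x1])
    return make_labelled(values, y)
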