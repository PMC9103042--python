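"""Synthetic imbalanced two-group RNA-seq count matrices with planted signal.

Counts are drawn from a negative-binomial model, the standard overdispersed
count distribution for bulk RNA-seq: gene g has a baseline mean mu_g drawn
log-uniformly over a wide dynamic range, and a shared dispersion d so that
var = mu + d * mu^2. A small planted set of differential genes has its tumor
mean multiplied by 2^LFC (up-regulated in tumor by default; a symmetric mode
flips half the planted genes down). The defaults mirror the shape of real
tumor/normal cohorts: thousands of genes, a couple hundred samples, and a
~9:1 tumor:normal imbalance.

Deliberately not modelled: library-size variation, gene-gene correlation and
batch effects — the generator isolates the marginal per-gene signal that the
KL selection and the classifier consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import (
    ExpressionMatrix,
    LabelledDataset,
    SampleLabels,
    write_expression_matrix,
)

logger = logging.getLogger("kldnet.synthetic_data")


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    log2_fold_change: planted tumor/normal log2 mean ratio.
    nb_dispersion: negative-binomial dispersion d in var = mu + d mu^2.
    base_mean_log_range: (low, high) of the log2 baseline means, drawn
        uniformly — covers lowly to highly expressed genes.
    symmetric: if True, half the planted genes are down-regulated instead.
    """

    n_genes: int = 2000
    n_tumor: int = 180
    n_normal: int = 20
    n_differential: int = 50
    log2_fold_change: float = 2.0
    nb_dispersion: float = 0.1
    base_mean_log_range: tuple[float, float] = (2.0, 12.0)
    seed: int = 0
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_differential < 0 or self.n_differential > self.n_genes:
            raise ValueError("n_differential must be in [0, n_genes]")
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("both group sizes must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.base_mean_log_range
        if not lo < hi:
            raise ValueError("base_mean_log_range must be (low, high) with low < high")


@dataclass
class SyntheticTruth:
    """The planted differential genes and their true log2 fold changes."""

    differential_gene_ids: set[str]
    log2_fold_changes: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.log2_fold_changes) != self.differential_gene_ids:
            raise ValueError("truth ids and fold-change keys must match")


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, size: tuple[int, int]
) -> np.ndarray:
    """Negative binomial parameterized by mean and dispersion (var = mu + d mu^2)."""
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size).astype(float)


def simulate(cfg: SimulationConfig | None = None) -> tuple[LabelledDataset, SyntheticTruth]:
    """Generate a labelled count matrix and its planted truth, deterministically."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    sample_ids = [f"tumor_{j:03d}" for j in range(cfg.n_tumor)] + [
        f"normal_{j:03d}" for j in range(cfg.n_normal)
    ]
    y = np.concatenate([np.ones(cfg.n_tumor, dtype=int), np.zeros(cfg.n_normal, dtype=int)])

    lo, hi = cfg.base_mean_log_range
    base_mean = 2.0 ** rng.uniform(lo, hi, size=cfg.n_genes)
    diff_idx = rng.choice(cfg.n_genes, size=cfg.n_differential, replace=False)
    lfc = np.zeros(cfg.n_genes)
    lfc[diff_idx] = cfg.log2_fold_change
    if cfg.symmetric and cfg.n_differential:
        flip = diff_idx[: cfg.n_differential // 2]
        lfc[flip] = -cfg.log2_fold_change

    tumor_mean = base_mean * 2.0 ** lfc
    values = np.empty((cfg.n_genes, cfg.n_tumor + cfg.n_normal))
    values[:, : cfg.n_tumor] = _nb_draw(
        rng, tumor_mean[:, None], cfg.nb_dispersion, (cfg.n_genes, cfg.n_tumor)
    )
    values[:, cfg.n_tumor :] = _nb_draw(
        rng, base_mean[:, None], cfg.nb_dispersion, (cfg.n_genes, cfg.n_normal)
    )

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    labels = SampleLabels(sample_ids, y)
    truth = SyntheticTruth(
        differential_gene_ids={gene_ids[i] for i in diff_idx},
        log2_fold_changes={gene_ids[i]: float(lfc[i]) for i in diff_idx},
    )
    logger.info(
        "simulated %d genes x %d samples (%d tumor / %d normal), %d planted at LFC %.2g",
        cfg.n_genes, len(sample_ids), cfg.n_tumor, cfg.n_normal,
        cfg.n_differential, cfg.log2_fold_change,
    )
    return LabelledDataset(matrix, labels, provenance=f"simulated seed={cfg.seed}"), truth


def write_fixture(
    ds: LabelledDataset, truth: SyntheticTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write matrix.tsv / labels.tsv / truth.tsv, round-trippable by expression_io."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.tsv",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_expression_matrix(ds.matrix, paths["matrix"])
    with open(paths["labels"], "w") as fh:
        for sid, lab in zip(ds.labels.sample_ids, ds.y):
            fh.write(f"{sid}\t{int(lab)}\n")
    with open(paths["truth"], "w") as fh:
        for g in sorted(truth.differential_gene_ids):
            fh.write(f"{g}\t{truth.log2_fold_changes[g]:.10g}\n")
    return paths


def read_truth(path: str | Path) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "lfc"], dtype={0: str})
    lfcs = {str(g): float(v) for g, v in zip(df["gene_id"], df["lfc"])}
    return SyntheticTruth(set(lfcs), lfcs)
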