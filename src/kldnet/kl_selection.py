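"""KL-divergence gene selection.

For every gene the expression values of the disease (tumor) group and the
control (normal) group are turned into a pair of binned probability
distributions P and Q over shared bin edges, and the gene is scored with the
Kullback-Leibler divergence

    D(P || Q) = sum_i P(i) * ln( P(i) / Q(i) )   >= 0   (nats)

which is zero iff P == Q. Genes whose score exceeds a threshold are selected
as disease-related features.

Density estimation uses equal-width histograms on log2(x+1)-transformed
values with a small additive pseudocount per bin, which keeps every Q(i)
strictly positive and the divergence finite. The pseudocount default (0.05)
keeps the total smoothing mass (one pseudo-observation across 20 bins) small
relative to control groups of a few dozen samples; heavier smoothing flattens
both distributions toward uniform and compresses the score scale so strongly
that a threshold of 3 nats becomes unreachable even for fully separated
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression_io import LabelledDataset

logger = logging.getLogger("kldnet.kl_selection")


@dataclass
class BinningConfig:
    """How per-gene distributions are estimated from finite samples.

    n_bins: number of equal-width histogram bins over the pooled range.
    transform: "log2p1" (log2(x+1), the variance-stabilizing default for
        counts) or "none".
    pseudocount: added to every bin count before normalization so both
        probability vectors are strictly positive.
    """

    n_bins: int = 20
    transform: str = "log2p1"
    pseudocount: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.transform not in ("none", "log2p1"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def apply_transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.transform == "log2p1":
            return np.log2(x + 1.0)
        return x


@dataclass
class DistributionPair:
    """Binned probability vectors for one gene: P (disease), Q (control)."""

    bin_edges: np.ndarray
    P: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        n = len(self.P)
        if len(self.Q) != n or len(self.bin_edges) != n + 1:
            raise ValueError("P, Q and bin_edges have inconsistent lengths")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        for name, v in (("P", self.P), ("Q", self.Q)):
            if np.any(v <= 0):
                raise ValueError(f"{name} has non-positive entries (missing pseudocount?)")
            if abs(v.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} does not sum to 1 (sum={v.sum()!r})")


@dataclass
class KLScoreTable:
    """Per-gene KL scores (nats) plus the binning used to produce them."""

    scores: dict[str, float]
    binning: BinningConfig

    def __post_init__(self) -> None:
        for g, s in self.scores.items():
            if not np.isfinite(s) or s < 0:
                raise ValueError(f"invalid score {s!r} for gene {g!r}")


@dataclass
class SelectionConfig:
    """Threshold and divergence direction for gene selection.

    direction: which group plays P in D(P||Q). "disease_vs_control" is the
    default (P = tumor); "symmetrized" averages both directions.
    """

    threshold: float = 3.0
    direction: str = "disease_vs_control"

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold) and self.threshold != float("inf") and self.threshold != float("-inf"):
            raise ValueError("threshold must not be NaN")
        if self.direction not in ("disease_vs_control", "control_vs_disease", "symmetrized"):
            raise ValueError(f"unknown direction {self.direction!r}")


def estimate_distribution_pair(
    disease_values: np.ndarray,
    control_values: np.ndarray,
    cfg: BinningConfig | None = None,
) -> DistributionPair:
    """Estimate smoothed binned distributions for one gene.

    Bin edges are equal-width over the pooled (transformed) min..max so both
    groups share the same support. A degenerate pooled range (all values
    identical) is widened to [v - 0.5, v + 0.5], which makes both histograms
    concentrate in the same bins and the downstream divergence exactly 0 —
    an invariant gene must never be selected.
    """
    cfg = cfg or BinningConfig()
    d = np.asarray(disease_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if d.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(d < 0) or np.any(c < 0):
        raise ValueError("expression values must be non-negative")
    d = cfg.apply_transform(d)
    c = cfg.apply_transform(c)
    lo = min(d.min(), c.min())
    hi = max(d.max(), c.max())
    if lo == hi:
        # degenerate pooled range: the gene is invariant, so both groups get
        # the same (uniform) distribution and the divergence is exactly 0
        edges = np.linspace(lo - 0.5, hi + 0.5, cfg.n_bins + 1)
        uniform = np.full(cfg.n_bins, 1.0 / cfg.n_bins)
        return DistributionPair(edges, uniform, uniform.copy())
    edges = np.linspace(lo, hi, cfg.n_bins + 1)
    p_counts, _ = np.histogram(d, bins=edges)
    q_counts, _ = np.histogram(c, bins=edges)
    P = (p_counts + cfg.pseudocount) / (p_counts.sum() + cfg.pseudocount * cfg.n_bins)
    Q = (q_counts + cfg.pseudocount) / (q_counts.sum() + cfg.pseudocount * cfg.n_bins)
    return DistributionPair(edges, P, Q)


def kl_divergence(pair: DistributionPair) -> float:
    """D(P || Q) = sum_i P(i) ln(P(i)/Q(i)) in nats, clamped at 0.

    Always >= 0 by Gibbs' inequality; tiny negative float residue from
    cancellation is clamped.
    """
    val = float(np.sum(pair.P * np.log(pair.P / pair.Q)))
    if val < -1e-12:  # genuine negativity means the invariants were broken upstream
        raise ValueError(f"negative KL divergence {val}; invalid distribution pair")
    return max(val, 0.0)


def score_genes(
    ds: LabelledDataset,
    bin_cfg: BinningConfig | None = None,
    sel_cfg: SelectionConfig | None = None,
) -> KLScoreTable:
    """Score every gene by the divergence between its tumor and normal distributions."""
    bin_cfg = bin_cfg or BinningConfig()
    sel_cfg = sel_cfg or SelectionConfig()
    y = ds.y
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present to score genes")
    tumor = ds.matrix.values[:, y == 1]
    normal = ds.matrix.values[:, y == 0]
    scores: dict[str, float] = {}
    for i, gene in enumerate(ds.matrix.gene_ids):
        pair = estimate_distribution_pair(tumor[i], normal[i], bin_cfg)
        if sel_cfg.direction == "disease_vs_control":
            s = kl_divergence(pair)
        elif sel_cfg.direction == "control_vs_disease":
            s = kl_divergence(DistributionPair(pair.bin_edges, pair.Q, pair.P))
        else:
            s = 0.5 * (
                kl_divergence(pair)
                + kl_divergence(DistributionPair(pair.bin_edges, pair.Q, pair.P))
            )
        scores[gene] = s
    return KLScoreTable(scores, bin_cfg)


def select_genes(table: KLScoreTable, cfg: SelectionConfig | None = None) -> list[str]:
    """Genes with score strictly above the threshold, by descending score.

    Ties are broken lexicographically by gene id so the output is a pure
    function of the table. May be empty.
    """
    cfg = cfg or SelectionConfig()
    hits = [(g, s) for g, s in table.scores.items() if s > cfg.threshold]
    hits.sort(key=lambda gs: (-gs[1], gs[0]))
    return [g for g, _ in hits]


def write_score_table(table: KLScoreTable, path: str | Path) -> Path:
    """Write gene_id<TAB>kl_score, descending by score."""
    path = Path(path)
    rows = sorted(table.scores.items(), key=lambda gs: (-gs[1], gs[0]))
    with open(path, "w") as fh:
        fh.write("gene_id\tkl_score\n")
        for g, s in rows:
            fh.write(f"{g}\t{s:.10g}\n")
    return path


def write_selection(genes: list[str], path: str | Path) -> Path:
    """Write the selected gene ids, one per line, in selection order."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
    return path
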