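"""Confusion-matrix metrics, ROC/AUC and stratified k-fold cross-validation.

The cross-validation protocol matters here because gene selection is part of
the model: under the default leak-free protocol the KL selection is re-fit
on each training fold only, so the held-out estimates are honest. The
alternative ``paper_protocol`` selects genes once on the full dataset before
splitting — the ordering many published pipelines use — which leaks
information from the held-out folds into the feature set and typically
inflates the estimates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .expression_io import ExpressionMatrix, LabelledDataset, SampleLabels
from .kl_selection import BinningConfig, SelectionConfig, score_genes, select_genes
from .neural_model import FocalLossConfig, NetworkConfig, TrainedModel, predict, train

logger = logging.getLogger("kldnet.evaluation")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Threshold metrics plus AUC. A metric whose denominator is zero is
    ``None`` (explicitly undefined), never silently 0 or NaN."""

    accuracy: float | None
    recall: float | None
    precision: float | None
    auc: float | None
    confusion: ConfusionMatrix
    threshold: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "auc": self.auc,
            "threshold": self.threshold,
            "confusion": dataclasses.asdict(self.confusion),
        }


@dataclass
class CVReport:
    k: int
    seed: int
    protocol: str
    folds: list[MetricsReport]
    mean: dict[str, float | None]
    std: dict[str, float | None]
    best_fold_index: int
    selected_gene_counts: list[int]
    roc_curves: list[list[tuple[float, float]]] = field(default_factory=list, repr=False)
    fold_models: list[TrainedModel] = field(default_factory=list, repr=False)
    fold_selections: list[list[str]] = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "protocol": self.protocol,
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean,
            "std": self.std,
            "best_fold_index": self.best_fold_index,
            "selected_gene_counts": self.selected_gene_counts,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)
        return path


def confusion_at_threshold(
    y: np.ndarray, yhat: np.ndarray, t: float = 0.5
) -> ConfusionMatrix:
    """Count TP/FP/TN/FN; a sample is predicted positive iff yhat >= t."""
    y = np.asarray(y, dtype=int)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat length mismatch")
    pred = yhat >= t
    actual = y == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & actual)),
        fp=int(np.sum(pred & ~actual)),
        tn=int(np.sum(~pred & ~actual)),
        fn=int(np.sum(~pred & actual)),
    )


def _safe_div(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix, threshold: float = 0.5) -> MetricsReport:
    """Accuracy = (TP+TN)/total, Recall = TP/(TP+FN), Precision = TP/(TP+FP)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=_safe_div(cm.tp + cm.tn, cm.total),
        recall=_safe_div(cm.tp, cm.tp + cm.fn),
        precision=_safe_div(cm.tp, cm.tp + cm.fp),
        auc=None,
        confusion=cm,
        threshold=threshold,
    )


def roc_auc(y: np.ndarray, yhat: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """AUC by the rank (Mann-Whitney) formulation, ties counted 1/2, plus the
    ROC curve swept over the observed score thresholds.

    The curve groups tied scores so its trapezoidal area equals the rank AUC
    exactly. Points are ordered by increasing FPR and include (0,0) and (1,1).
    """
    y = np.asarray(y, dtype=int)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat length mismatch")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes")
    ranks = rankdata(yhat)  # average ranks handle ties as 1/2
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-yhat, kind="stable")
    ys = y[order]
    scores = yhat[order]
    curve = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(ys):
        j = i
        while j < len(ys) and scores[j] == scores[i]:  # consume a tie group
            tp += int(ys[j] == 1)
            fp += int(ys[j] == 0)
            j += 1
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    return float(auc), curve


def write_roc_curve(curve: list[tuple[float, float]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in curve:
            fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")
    return path


def _subset_dataset(ds: LabelledDataset, cols: np.ndarray, genes: list[str] | None = None) -> LabelledDataset:
    m = ds.matrix
    if genes is None:
        rows = np.arange(m.n_genes)
        gene_ids = list(m.gene_ids)
    else:
        index = {g: i for i, g in enumerate(m.gene_ids)}
        rows = np.array([index[g] for g in genes])
        gene_ids = list(genes)
    sub = ExpressionMatrix(
        gene_ids, [m.sample_ids[j] for j in cols], m.values[np.ix_(rows, cols)]
    )
    lab = SampleLabels([m.sample_ids[j] for j in cols], ds.y[cols])
    return LabelledDataset(sub, lab, provenance=ds.provenance)


def _aggregate(folds: list[MetricsReport]) -> tuple[dict, dict]:
    mean: dict[str, float | None] = {}
    std: dict[str, float | None] = {}
    for name in ("accuracy", "recall", "precision", "auc"):
        vals = [getattr(f, name) for f in folds if getattr(f, name) is not None]
        mean[name] = float(np.mean(vals)) if vals else None
        std[name] = float(np.std(vals)) if vals else None
    return mean, std


def stratified_kfold_cv(
    ds: LabelledDataset,
    bin_cfg: BinningConfig | None = None,
    sel_cfg: SelectionConfig | None = None,
    net_cfg: NetworkConfig | None = None,
    loss_cfg: FocalLossConfig | None = None,
    k: int = 5,
    seed: int = 0,
    protocol: str = "leak_free",
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold cross-validation of the full selection + training
    pipeline.

    Per fold: genes are selected (on the training fold only under
    ``leak_free``; once on the full data under ``paper_protocol``), the
    network is trained on the training fold, and metrics are computed on the
    held-out fold. The best model is the one with the highest held-out AUC
    (ties go to the earlier fold). ``net_cfg.input_dim`` is overridden per
    fold by the selected gene count; the fold training seed is derived from
    ``seed`` and the fold index.
    """
    bin_cfg = bin_cfg or BinningConfig()
    sel_cfg = sel_cfg or SelectionConfig()
    net_cfg = net_cfg or NetworkConfig(input_dim=1)
    loss_cfg = loss_cfg or FocalLossConfig()
    if protocol not in ("leak_free", "paper_protocol"):
        raise ValueError(f"unknown protocol {protocol!r}")
    y = ds.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} samples, have {counts[1]} tumor / {counts[0]} normal"
        )

    global_selection: list[str] | None = None
    if protocol == "paper_protocol":
        global_selection = select_genes(score_genes(ds, bin_cfg, sel_cfg), sel_cfg)
        if not global_selection:
            raise ValueError("gene selection is empty at this threshold")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[MetricsReport] = []
    roc_curves: list[list[tuple[float, float]]] = []
    models: list[TrainedModel] = []
    selections: list[list[str]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_ds = _subset_dataset(ds, train_idx)
        if protocol == "leak_free":
            selected = select_genes(score_genes(train_ds, bin_cfg, sel_cfg), sel_cfg)
            if not selected:
                raise ValueError(
                    f"fold {fold}: gene selection is empty at threshold "
                    f"{sel_cfg.threshold}; lower the threshold"
                )
        else:
            selected = global_selection
        fold_seed = (seed * 100003 + 7919 * fold + net_cfg.seed) % (2**31)
        fold_net = dataclasses.replace(
            net_cfg, input_dim=len(selected), seed=fold_seed
        )
        model = train(_subset_dataset(ds, train_idx, selected), fold_net, loss_cfg)
        test_ds = _subset_dataset(ds, test_idx, selected)
        yhat = predict(model, test_ds.matrix.values.T)
        cm = confusion_at_threshold(test_ds.y, yhat, threshold)
        rep = metrics(cm, threshold)
        rep.auc, curve = roc_auc(test_ds.y, yhat)
        folds.append(rep)
        roc_curves.append(curve)
        models.append(model)
        selections.append(list(selected))
        logger.info(
            "fold %d: %d genes, auc=%.4f acc=%s", fold, len(selected), rep.auc,
            f"{rep.accuracy:.4f}" if rep.accuracy is not None else "NA",
        )

    mean, std = _aggregate(folds)
    aucs = [f.auc if f.auc is not None else -1.0 for f in folds]
    best = int(np.argmax(aucs))
    return CVReport(
        k=k,
        seed=seed,
        protocol=protocol,
        folds=folds,
        mean=mean,
        std=std,
        best_fold_index=best,
        selected_gene_counts=[len(s) for s in selections],
        roc_curves=roc_curves,
        fold_models=models,
        fold_selections=selections,
    )
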