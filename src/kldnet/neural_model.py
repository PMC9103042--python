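"""Two-hidden-layer neural classifier with cross-entropy and focal losses.

The model maps a standardized expression vector x to a disease probability

    h1 = relu(x W1 + b1)
    h2 = relu(h1 W2 + b2)
    yhat = sigmoid(h2 . w3 + b3)

with relu(x) = max(x, 0) and sigmoid(x) = 1 / (1 + e^-x). A *strict* mode
reproduces the bias-free literal architecture in which the sigmoid is applied
to the second layer itself (its width forced to 1, no output weight vector):
yhat = sigmoid(relu(x W1) W2).

Two objectives are available, both averaged over samples, with y = 1 for
tumor and 0 for normal:

    cross-entropy:  -y log(yhat) - (1 - y) log(1 - yhat)
    focal:          -y a (1 - yhat)^g log(yhat) - (1 - y) yhat^g log(1 - yhat)

The focal loss down-weights confidently classified samples through the
(1 - yhat)^g / yhat^g modulating factors so that hard samples dominate the
gradient under class imbalance; a rebalances the positive class. The form
above ("as_printed") carries no (1 - a) factor on the negative term; the
"standard" variant adds it, matching the common focal-loss formulation.

Training is plain Adam on the analytic backprop gradients; everything is
deterministic given the seed (fixed init, fixed shuffle order), so two runs
with the same configuration produce bit-identical parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .expression_io import LabelledDataset

logger = logging.getLogger("kldnet.neural_model")

CHECKPOINT_SCHEMA = 1
#: probabilities are clipped to [EPS, 1-EPS] before logs
EPS = 1e-7


@dataclass
class NetworkConfig:
    input_dim: int
    hidden_sizes: tuple[int, int] = (64, 16)
    seed: int = 0
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    loss: str = "focal"
    standardize: str = "log2p1_zscore"
    strict_output: bool = False

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if len(self.hidden_sizes) != 2 or min(self.hidden_sizes) < 1:
            raise ValueError("hidden_sizes must be a pair of positive ints")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.standardize not in ("none", "log2p1_zscore"):
            raise ValueError(f"unknown standardize mode {self.standardize!r}")
        if self.strict_output and self.hidden_sizes[1] != 1:
            raise ValueError("strict_output requires hidden_sizes[1] == 1")


@dataclass
class FocalLossConfig:
    """alpha in (0, 1] rebalances the positive class; gamma >= 0 focuses on
    hard samples (gamma = 0, alpha = 1 recovers cross-entropy)."""

    alpha: float = 0.25
    gamma: float = 2.0
    variant: str = "as_printed"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.variant not in ("as_printed", "standard"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ModelParameters:
    """Network weights plus the feature-standardization statistics captured
    at fit time, so prediction is self-contained."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: float
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    standardize: str = "none"

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        self.w3 = np.asarray(self.w3, dtype=float)
        self.b3 = float(self.b3)
        d, h1 = self.W1.shape
        if self.W2.shape != (h1, len(self.b2)) or len(self.b1) != h1:
            raise ValueError("inconsistent parameter shapes")
        if len(self.w3) != self.W2.shape[1]:
            raise ValueError("w3 length must equal the second hidden width")
        for a in (self.W1, self.b1, self.W2, self.b2, self.w3):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite parameter values")

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]


@dataclass
class TrainedModel:
    params: ModelParameters
    config: NetworkConfig
    loss_cfg: FocalLossConfig
    training_loss_trace: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# forward pass and losses


def _clip(yhat: np.ndarray) -> np.ndarray:
    return np.clip(yhat, EPS, 1.0 - EPS)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(X: np.ndarray, p: ModelParameters, strict: bool = False) -> np.ndarray:
    """Probability outputs of the network; strictly inside (0, 1).

    ``X`` must already be standardized with the statistics stored in ``p``
    (see :func:`predict` for the user-facing entry point).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != p.input_dim:
        raise ValueError(f"X must be n x {p.input_dim}, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    z1 = X @ p.W1 + p.b1
    h1 = np.maximum(z1, 0.0)
    z2 = h1 @ p.W2 + p.b2
    if strict:
        yhat = _sigmoid(z2[:, 0])
    else:
        h2 = np.maximum(z2, 0.0)
        yhat = _sigmoid(h2 @ p.w3 + p.b3)
    # sigmoid saturates to exactly 0/1 in floats for |z| ~ 40; keep the
    # contract that outputs live in the open interval
    return np.clip(yhat, 1e-15, 1.0 - 1e-15)


def cross_entropy_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean binary cross-entropy, probabilities clipped to [EPS, 1-EPS]."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat length mismatch")
    yc = _clip(yhat)
    return float(np.mean(-y * np.log(yc) - (1.0 - y) * np.log(1.0 - yc)))


def focal_loss(y: np.ndarray, yhat: np.ndarray, cfg: FocalLossConfig | None = None) -> float:
    """Mean focal loss; ``variant="as_printed"`` leaves the negative-class
    term un-weighted by alpha, ``"standard"`` multiplies it by (1 - alpha)."""
    cfg = cfg or FocalLossConfig()
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat length mismatch")
    yc = _clip(yhat)
    neg_w = (1.0 - cfg.alpha) if cfg.variant == "standard" else 1.0
    pos = -y * cfg.alpha * (1.0 - yc) ** cfg.gamma * np.log(yc)
    neg = -(1.0 - y) * neg_w * yc ** cfg.gamma * np.log(1.0 - yc)
    return float(np.mean(pos + neg))


def _dloss_dyhat(
    y: np.ndarray, yhat: np.ndarray, loss: str, cfg: FocalLossConfig
) -> np.ndarray:
    """Per-sample d(loss_i)/d(yhat_i), zero where the clip is active."""
    yc = _clip(yhat)
    if loss == "cross_entropy":
        g = -y / yc + (1.0 - y) / (1.0 - yc)
    else:
        a, gam = cfg.alpha, cfg.gamma
        neg_w = (1.0 - a) if cfg.variant == "standard" else 1.0
        # d/dyhat of -a(1-p)^g log p   and of  -p^g log(1-p)
        gpos = a * (gam * (1.0 - yc) ** (gam - 1.0) * np.log(yc) - (1.0 - yc) ** gam / yc)
        gneg = neg_w * (-gam * yc ** (gam - 1.0) * np.log(1.0 - yc) + yc ** gam / (1.0 - yc))
        g = y * gpos + (1.0 - y) * gneg
    return np.where((yhat > EPS) & (yhat < 1.0 - EPS), g, 0.0)


def loss_and_gradients(
    X: np.ndarray,
    y: np.ndarray,
    p: ModelParameters,
    loss: str = "focal",
    loss_cfg: FocalLossConfig | None = None,
    strict: bool = False,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean loss on (X, y) and its analytic gradients w.r.t. every parameter."""
    loss_cfg = loss_cfg or FocalLossConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    z1 = X @ p.W1 + p.b1
    h1 = np.maximum(z1, 0.0)
    z2 = h1 @ p.W2 + p.b2
    if strict:
        yhat = _sigmoid(z2[:, 0])
    else:
        h2 = np.maximum(z2, 0.0)
        z3 = h2 @ p.w3 + p.b3
        yhat = _sigmoid(z3)

    loss_val = (
        cross_entropy_loss(y, yhat)
        if loss == "cross_entropy"
        else focal_loss(y, yhat, loss_cfg)
    )
    # delta = dL/dz at the sigmoid input, already averaged over samples
    delta = _dloss_dyhat(y, yhat, loss, loss_cfg) * yhat * (1.0 - yhat) / n
    if strict:
        gw3 = np.zeros_like(p.w3)
        gb3 = 0.0
        dz2 = delta[:, None]
    else:
        gw3 = h2.T @ delta
        gb3 = float(delta.sum())
        dz2 = np.outer(delta, p.w3) * (z2 > 0)
    gW2 = h1.T @ dz2
    gb2 = dz2.sum(axis=0)
    dz1 = (dz2 @ p.W2.T) * (z1 > 0)
    gW1 = X.T @ dz1
    gb1 = dz1.sum(axis=0)
    if strict:  # literal architecture trains weight matrices only, no biases
        gb1 = np.zeros_like(gb1)
        gb2 = np.zeros_like(gb2)
    grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "w3": gw3, "b3": gb3}
    return loss_val, grads


# ---------------------------------------------------------------------------
# standardization, initialization, training


def _fit_standardizer(X: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    if mode == "none":
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    Xt = np.log2(X + 1.0)
    mean = Xt.mean(axis=0)
    scale = Xt.std(axis=0)
    scale[scale == 0] = 1.0  # constant features pass through centred
    return mean, scale


def _apply_standardizer(X: np.ndarray, p: ModelParameters) -> np.ndarray:
    if p.standardize == "none":
        return np.asarray(X, dtype=float)
    return (np.log2(np.asarray(X, dtype=float) + 1.0) - p.feature_mean) / p.feature_scale


def _init_parameters(cfg: NetworkConfig, rng: np.random.Generator) -> ModelParameters:
    d, (h1, h2) = cfg.input_dim, cfg.hidden_sizes
    W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h1))
    W2 = rng.normal(0.0, np.sqrt(2.0 / h1), size=(h1, h2))
    w3 = rng.normal(0.0, np.sqrt(1.0 / h2), size=h2)
    return ModelParameters(
        W1, np.zeros(h1), W2, np.zeros(h2), w3, 0.0, standardize=cfg.standardize
    )


def train(
    ds: LabelledDataset,
    net_cfg: NetworkConfig,
    loss_cfg: FocalLossConfig | None = None,
) -> TrainedModel:
    """Fit the network on a labelled dataset (already restricted to the
    selected genes) with Adam.

    Deterministic given ``net_cfg.seed``: parameter init and per-epoch
    shuffles come from one seeded generator. The per-epoch full-data loss is
    recorded in ``training_loss_trace`` (entry 0 is the pre-training loss).
    Raises ``RuntimeError`` if the loss goes non-finite.
    """
    loss_cfg = loss_cfg or FocalLossConfig()
    y = ds.y.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("training data must contain both classes")
    if net_cfg.input_dim != ds.matrix.n_genes:
        raise ValueError(
            f"input_dim {net_cfg.input_dim} != {ds.matrix.n_genes} genes in dataset"
        )
    X_raw = ds.matrix.values.T  # samples x genes
    rng = np.random.default_rng(net_cfg.seed)
    params = _init_parameters(net_cfg, rng)
    params.feature_mean, params.feature_scale = _fit_standardizer(
        X_raw, net_cfg.standardize
    )
    X = _apply_standardizer(X_raw, params)

    n = len(y)
    bs = min(net_cfg.batch_size, n)
    names = ["W1", "b1", "W2", "b2", "w3", "b3"]
    m_adam = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float)) for k in names}
    v_adam = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float)) for k in names}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0

    def full_loss() -> float:
        yhat = forward(X, params, strict=net_cfg.strict_output)
        if net_cfg.loss == "cross_entropy":
            return cross_entropy_loss(y, yhat)
        return focal_loss(y, yhat, loss_cfg)

    trace = [full_loss()]
    for epoch in range(net_cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            _, grads = loss_and_gradients(
                X[idx], y[idx], params, net_cfg.loss, loss_cfg, net_cfg.strict_output
            )
            step += 1
            for k in names:
                g = np.asarray(grads[k], dtype=float)
                m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * g
                v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g * g
                mhat = m_adam[k] / (1 - beta1**step)
                vhat = v_adam[k] / (1 - beta2**step)
                upd = net_cfg.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
                cur = getattr(params, k)
                if k == "b3":
                    params.b3 = float(cur - upd)
                else:
                    setattr(params, k, cur - upd)
        epoch_loss = full_loss()
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"training loss became non-finite at epoch {epoch + 1} "
                f"(lr={net_cfg.learning_rate}); lower the learning rate"
            )
        trace.append(epoch_loss)
    logger.info(
        "trained %d epochs: loss %.6g -> %.6g", net_cfg.epochs, trace[0], trace[-1]
    )
    return TrainedModel(params, net_cfg, loss_cfg, np.array(trace))


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Disease probabilities for raw (unstandardized) feature rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.params.input_dim:
        raise ValueError(f"X must be n x {model.params.input_dim}, got {X.shape}")
    Xs = _apply_standardizer(X, model.params)
    return forward(Xs, model.params, strict=model.config.strict_output)


# ---------------------------------------------------------------------------
# checkpoint I/O


def save_checkpoint(model: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    p = model.params
    payload = {
        "schema_version": CHECKPOINT_SCHEMA,
        "network": {**asdict(model.config), "hidden_sizes": list(model.config.hidden_sizes)},
        "focal": asdict(model.loss_cfg),
        "weights": {
            "W1": p.W1.tolist(),
            "b1": p.b1.tolist(),
            "W2": p.W2.tolist(),
            "b2": p.b2.tolist(),
            "w3": p.w3.tolist(),
            "b3": p.b3,
        },
        "standardization": {
            "mode": p.standardize,
            "feature_mean": None if p.feature_mean is None else p.feature_mean.tolist(),
            "feature_scale": None if p.feature_scale is None else p.feature_scale.tolist(),
        },
        "training_loss_trace": model.training_loss_trace.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


def load_checkpoint(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {payload.get('schema_version')!r}")
    net = payload["network"]
    net["hidden_sizes"] = tuple(net["hidden_sizes"])
    cfg = NetworkConfig(**net)
    loss_cfg = FocalLossConfig(**payload["focal"])
    w = payload["weights"]
    std = payload["standardization"]
    params = ModelParameters(
        np.array(w["W1"]), np.array(w["b1"]), np.array(w["W2"]), np.array(w["b2"]),
        np.array(w["w3"]), w["b3"],
        feature_mean=None if std["feature_mean"] is None else np.array(std["feature_mean"]),
        feature_scale=None if std["feature_scale"] is None else np.array(std["feature_scale"]),
        standardize=std["mode"],
    )
    return TrainedModel(params, cfg, loss_cfg, np.array(payload["training_loss_trace"]))


def write_training_log(model: TrainedModel, path: str | Path) -> Path:
    """Per-epoch TSV ``epoch<TAB>loss`` (epoch 0 = before training)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("epoch\tloss\n")
        for e, v in enumerate(model.training_loss_trace):
            fh.write(f"{e}\t{v:.10g}\n")
    return path
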