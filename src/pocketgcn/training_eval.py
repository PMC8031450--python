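"""Training loop (Adam, MSE, early stopping) and regression metrics.

Training minimizes mean squared error between predicted and measured
affinities with Adam at the configured learning rate, monitors validation MSE
each epoch, stops after ``patience`` epochs without improvement, and restores
the best-validation weights. Everything is reproducible from the config seed.

Evaluation reports the four standard scoring-function metrics: RMSE, MAE,
Pearson correlation, and SD — the root mean squared residual (with an N−1
denominator) around the least-squares regression line of measured on
predicted affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .featurizer import PocketGraph
from .gcn import Network, backward_batch, forward_batch, stack_graphs


class DivergenceError(RuntimeError):
    """Validation loss became non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 200
    batch_size: int = 64
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.patience < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("patience, batch_size and max_epochs must be ≥ 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


@dataclass
class EvalReport:
    rmse: float
    mae: float
    pearson_r: float
    sd: float
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "pearson_r": self.pearson_r,
                "sd": self.sd, "n": self.n}


# ---------------------------------------------------------------------------
# Adam


class _Adam:
    """Standard Adam with default moment coefficients; only the learning rate
    is configurable."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


# ---------------------------------------------------------------------------
# Training


def _batched_predictions(net: Network, X, A_hat, mask, batch_size: int = 256) -> np.ndarray:
    preds = []
    for start in range(0, X.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        p, _ = forward_batch(net, X[sl], A_hat[sl], mask[sl], drop_rng=None)
        preds.append(p)
    return np.concatenate(preds)


def train(
    net: Network,
    train_graphs: list[PocketGraph],
    val_graphs: list[PocketGraph],
    cfg: TrainConfig,
) -> tuple[Network, TrainHistory]:
    """Train in place on MSE; returns (best-validation network, history).

    Per-epoch shuffling and dropout draws are seeded from ``cfg.seed``; two
    runs with the same seed and data produce identical histories. Docking
    poses, when attached upstream, are simply additional graphs carrying
    their parent complex's label.
    """
    if not train_graphs or not val_graphs:
        raise ValueError("train and validation sets must be non-empty")
    n_bins = net.config.n_bins
    for g in train_graphs + val_graphs:
        if g.n_bins != n_bins:
            raise ValueError(f"graph {g.id} has {g.n_bins} bins, network expects {n_bins}")

    Xt, At, mt, yt, _ = stack_graphs(train_graphs)
    Xv, Av, mv, yv, _ = stack_graphs(val_graphs)

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(net.params, cfg.learning_rate)
    history = TrainHistory()
    best_val = math.inf
    best_params = None
    n_train = Xt.shape[0]

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred, cache = forward_batch(net, Xt[idx], At[idx], mt[idx], drop_rng=rng)
            err = pred - yt[idx]
            epoch_loss += float(err @ err)
            dpred = 2.0 * err / len(idx)
            grads = backward_batch(net, cache, dpred)
            opt.step(net.params, grads)
        history.train_loss.append(epoch_loss / n_train)

        val_pred = _batched_predictions(net, Xv, Av, mv)
        val_loss = float(np.mean((val_pred - yv) ** 2))
        if not math.isfinite(val_loss):
            raise DivergenceError(f"validation loss non-finite at epoch {epoch}")
        history.val_loss.append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_params = {k: v.copy() for k, v in net.params.items()}
        elif epoch - history.best_epoch >= cfg.patience:
            history.stopped_early = True
            break

    net.params = best_params if best_params is not None else net.params
    return net, history


def predict(net: Network, graphs: list[PocketGraph]) -> list[tuple[str, float]]:
    """Eval-mode predictions, one (id, value) per graph, order preserved."""
    if not graphs:
        return []
    X, A_hat, mask, _, ids = stack_graphs(graphs)
    preds = _batched_predictions(net, X, A_hat, mask)
    return list(zip(ids, (float(p) for p in preds)))


# ---------------------------------------------------------------------------
# Metrics


def sd_metric(predicted, measured) -> float:
    """Root mean squared residual around the least-squares line of measured
    on predicted affinity, with an N−1 denominator:

        SD = sqrt( sum_i (y_i − (a + b·x_i))² / (N − 1) )

    where x are predictions, y measurements, and (a, b) the fitted intercept
    and slope.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"SD needs at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("regression line undefined: predictions have zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return float(np.sqrt(resid @ resid / (n - 1)))


def evaluate(predicted, measured) -> EvalReport:
    """RMSE, MAE, Pearson R and SD for a prediction set.

    RMSE and MAE are always computed (n ≥ 2). The correlation metrics need a
    regression line: with fewer than 3 pairs or zero variance in either
    vector, Pearson R and SD are reported as NaN rather than invented.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if len(x) != len(y):
        raise ValueError("predicted and measured lengths differ")
    if len(x) < 2:
        raise ValueError(f"evaluation needs at least 2 pairs, got {len(x)}")
    diff = x - y
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    mae = float(np.mean(np.abs(diff)))
    if rmse == 0.0 and len(x) >= 3 and np.ptp(x) > 0:
        # perfect prediction: correlation 1 by construction, residuals vanish
        return EvalReport(rmse=0.0, mae=0.0, pearson_r=1.0, sd=0.0, n=len(x))
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return EvalReport(rmse=rmse, mae=mae, pearson_r=math.nan, sd=math.nan, n=len(x))
    r = float(stats.pearsonr(x, y).statistic)
    return EvalReport(rmse=rmse, mae=mae, pearson_r=r, sd=sd_metric(x, y), n=len(x))
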