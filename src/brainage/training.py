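"""Optimization recipe: composite loss, warmup + cosine schedule, early
stopping on validation MAE, optional backbone freezing, batch prediction.

The objective couples a primary mean-squared-error regression loss with a
small auxiliary pairwise margin ranking loss (weight ``lambda_rank``,
margin ``beta_margin``) that rewards predictions ordered like the true
ages within each batch.  The learning rate warms up linearly for
``warmup_epochs`` and then follows cosine annealing down to ``min_lr``;
training stops once the validation MAE has not strictly improved for
``patience`` epochs and the best-validation checkpoint is returned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .metrics import PredictionSet
from .nn import Tensor, AdamW
from .nn.modules import BatchNorm3d


@dataclass
class TrainConfig:
    batch_size: int = 8
    peak_lr: float = 2e-4
    warmup_start_lr: float = 1e-6
    warmup_epochs: int = 5
    min_lr: float = 1e-5
    max_epochs: int = 100
    patience: int = 15
    weight_decay: float = 1e-5
    betas: tuple = (0.9, 0.999)
    eps: float = 1e-8
    lambda_rank: float = 0.005
    beta_margin: float = 0.5
    decay_all_params: bool = True      # off: exempt norms/biases/gates from decay
    freeze_backbone_epochs: int = 0    # >0: train head only for this many epochs first
    init_output_bias: bool = True      # start the output at the train-set mean age
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_lr <= self.peak_lr):
            raise ValueError("need 0 < min_lr <= peak_lr")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.lambda_rank < 0:
            raise ValueError("lambda_rank must be >= 0")


def composite_loss(pred: Tensor, true_ages: np.ndarray,
                   lambda_rank: float = 0.005, beta_margin: float = 0.5) -> Tensor:
    """MSE + lambda * pairwise margin ranking loss over within-batch pairs.

    The ranking term averages max(0, beta - sign(y_i - y_j) (yhat_i - yhat_j))
    over all ordered pairs with distinct true ages; it is zero for batches
    with fewer than two distinct ages.
    """
    y = np.asarray(true_ages, dtype=pred.data.dtype)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(pred.data)):
        raise ValueError("non-finite ages or predictions in loss")
    n = y.shape[0]
    mse = ((pred - Tensor(y)) ** 2.0).mean()
    if lambda_rank == 0.0:
        return mse
    sign = np.sign(y[:, None] - y[None, :])
    mask = (sign != 0).astype(pred.data.dtype)
    count = mask.sum()
    if count == 0:
        return mse
    diff = pred.reshape(n, 1) - pred.reshape(1, n)
    hinge = (Tensor(np.full((n, n), beta_margin, pred.data.dtype))
             - Tensor(sign.astype(pred.data.dtype)) * diff).relu()
    rank = (hinge * Tensor(mask)).sum() * (1.0 / count)
    return mse + lambda_rank * rank


def lr_at(step: int, steps_per_epoch: int, cfg: TrainConfig) -> float:
    """Linear warmup to peak_lr, then cosine annealing to min_lr.

    The final step of the last epoch lands exactly on min_lr.
    """
    warm = cfg.warmup_epochs * steps_per_epoch
    total = cfg.max_epochs * steps_per_epoch
    if step < warm:
        return cfg.warmup_start_lr + (cfg.peak_lr - cfg.warmup_start_lr) * step / warm
    span = max(total - 1 - warm, 1)
    t = min((step - warm) / span, 1.0)
    return cfg.min_lr + 0.5 * (cfg.peak_lr - cfg.min_lr) * (1.0 + math.cos(math.pi * t))


def freeze_backbone_schedule(model, phase: str):
    """`frozen`: exclude backbone parameters from optimization and hold its
    normalization statistics fixed; `joint`: everything trainable."""
    if phase not in ("frozen", "joint"):
        raise ValueError(f"phase must be 'frozen' or 'joint', got {phase!r}")
    backbone = getattr(model, "backbone", None)
    if backbone is None:
        return model
    frozen = phase == "frozen"
    for p in backbone.parameters():
        p.requires_grad = not frozen
    for m in backbone.modules():
        if isinstance(m, BatchNorm3d):
            m.frozen_stats = frozen
    return model


def _set_output_bias(model, value: float) -> None:
    last = None
    for name, p in model.named_parameters():
        if name.endswith("fc2.bias") or name.endswith("fc.bias"):
            last = p
    if last is not None and last.data.size == 1:
        last.data[:] = value


def _make_optimizer(model, cfg: TrainConfig, lr: float) -> AdamW:
    no_decay = ()
    if not cfg.decay_all_params:
        no_decay = {n for n, p in model.named_parameters()
                    if p.data.ndim <= 1 or "bn" in n or "ln" in n or "gate" in n}
    named = [(n, p) for n, p in model.named_parameters() if p.requires_grad]
    return AdamW(named, lr=lr, betas=cfg.betas, eps=cfg.eps,
                 weight_decay=cfg.weight_decay, no_decay=no_decay)


def _forward_batches(model, vols: np.ndarray, batch_size: int) -> np.ndarray:
    out = []
    for i in range(0, len(vols), batch_size):
        x = Tensor(vols[i:i + batch_size, None].astype(np.float32))
        out.append(model(x).data.astype(np.float64))
    return np.concatenate(out)


def predict(model, vols: np.ndarray, manifest=None, batch_size: int = 8) -> PredictionSet:
    """Deterministic batched prediction in evaluation mode."""
    model.eval()
    preds = _forward_batches(model, np.asarray(vols), batch_size)
    if manifest is not None:
        recs = list(manifest)
        if len(recs) != len(preds):
            raise ValueError(f"{len(recs)} manifest records vs {len(preds)} volumes")
        return PredictionSet([r.scan_id for r in recs], [r.age for r in recs],
                             preds, [r.subject_id for r in recs])
    return PredictionSet([f"scan-{i}" for i in range(len(preds))],
                         np.zeros(len(preds)), preds)


def train(model, train_set, val_set, cfg: TrainConfig | None = None,
          history_path=None):
    """Fit `model`; returns (best_state_dict, history).

    `train_set` / `val_set` are (volumes, ages) with volumes (N, D, H, W).
    The checkpoint with the lowest validation MAE is returned; training
    stops early once that MAE has not improved by more than 1e-6 for
    `patience` consecutive epochs.
    """
    cfg = cfg or TrainConfig()
    tx, ty = np.asarray(train_set[0]), np.asarray(train_set[1], dtype=np.float64)
    vx, vy = np.asarray(val_set[0]), np.asarray(val_set[1], dtype=np.float64)
    if len(tx) == 0 or len(vx) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    model.seed_stochastic(int(rng.integers(2 ** 31)))
    if cfg.init_output_bias:
        _set_output_bias(model, float(ty.mean()))
    steps_per_epoch = max(1, math.ceil(len(tx) / cfg.batch_size))

    phase = "joint"
    if cfg.freeze_backbone_epochs > 0:
        phase = "frozen"
        freeze_backbone_schedule(model, "frozen")
    opt = _make_optimizer(model, cfg, cfg.warmup_start_lr)

    history: list[dict] = []
    best = {"val_mae": math.inf, "epoch": -1, "state": None}
    step = 0
    stale = 0
    for epoch in range(cfg.max_epochs):
        if phase == "frozen" and epoch >= cfg.freeze_backbone_epochs:
            phase = "joint"
            freeze_backbone_schedule(model, "joint")
            opt = _make_optimizer(model, cfg, opt.lr)
        model.train()
        order = rng.permutation(len(tx))
        losses = []
        for i in range(0, len(tx), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            x = Tensor(tx[idx][:, None].astype(np.float32))
            pred = model(x)
            loss = composite_loss(pred, ty[idx], cfg.lambda_rank, cfg.beta_margin)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            loss.backward()
            opt.lr = lr_at(step, steps_per_epoch, cfg)
            opt.step()
            losses.append(float(loss.data))
            step += 1
        model.eval()
        val_pred = _forward_batches(model, vx, cfg.batch_size)
        val_mae = float(np.mean(np.abs(val_pred - vy)))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_mae": val_mae, "lr": opt.lr, "phase": phase})
        if val_mae < best["val_mae"] - 1e-6:
            best = {"val_mae": val_mae, "epoch": epoch, "state": model.state_dict()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    if history_path is not None:
        Path(history_path).parent.mkdir(parents=True, exist_ok=True)
        with open(history_path, "w") as fh:
            for row in history:
                fh.write(json.dumps(row) + "\n")
    return best, history
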