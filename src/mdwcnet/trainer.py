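"""Training recipe: cross-entropy, SGD with step-decayed learning rate.

The optimisation protocol is deliberately plain: mini-batch SGD with
momentum 0.9, initial learning rate 1e-3 cut by 10x every 20 epochs, batch
size 8, 100 epochs, unweighted pixel cross-entropy, and random horizontal
flipping of training samples.  Model selection keeps the checkpoint with
the best validation Dice.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import sys
import time
from pathlib import Path

import numpy as np

from . import nn
from .architecture import MDWCNet, save_checkpoint
from .data import SegmentationDataset
from .errors import InvalidInputError
from .metrics import image_metrics

logger = logging.getLogger("mdwcnet")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 8
    epochs: int = 100
    lr0: float = 1e-3
    lr_step: int = 20
    lr_gamma: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 0.0
    flip_prob: float = 0.5
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.lr0 <= 0 or not (0 < self.lr_gamma <= 1) or self.batch_size < 1:
            raise InvalidInputError("need lr0 > 0, 0 < lr_gamma <= 1, batch_size >= 1")
        if self.epochs < 1 or self.lr_step < 1:
            raise InvalidInputError("epochs and lr_step must be positive")

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: ``lr0 * gamma ** floor(epoch / lr_step)``."""
    if epoch < 0 or epoch >= cfg.epochs:
        raise InvalidInputError(f"epoch {epoch} outside [0, {cfg.epochs})")
    return cfg.lr0 * cfg.lr_gamma ** (epoch // cfg.lr_step)


def ce_loss(logits: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pixel cross-entropy and its gradient w.r.t. the logits.

    ``logits`` is (N, num_classes, H, W); ``mask`` (N, H, W) with integer
    labels.  Uses the max-shifted log-sum-exp for stability.
    """
    if logits.ndim != 4 or mask.shape != (logits.shape[0],) + logits.shape[2:]:
        raise InvalidInputError(f"shape mismatch: logits {logits.shape}, mask {mask.shape}")
    ncls = logits.shape[1]
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= ncls:
        raise InvalidInputError(f"labels must lie in [0, {ncls})")
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    onehot = np.eye(ncls, dtype=nn.DTYPE)[mask].transpose(0, 3, 1, 2)
    npix = mask.size
    loss = float(-(logp * onehot).sum() / npix)
    grad = (np.exp(logp) - onehot) / npix
    return loss, grad.astype(nn.DTYPE)


def predict(net: MDWCNet, image: np.ndarray) -> np.ndarray:
    """Binary mask via argmax over the class logits (ties go to class 0)."""
    if image.ndim == 3:
        image = image[None]
    logits = net.forward(image, train=False)
    if logits.shape[1] != net.cfg.num_classes:
        raise InvalidInputError("unexpected logits channel count")
    out = logits.argmax(axis=1).astype(np.uint8)
    return out[0] if out.shape[0] == 1 else out


def evaluate_split(net: MDWCNet, ds: SegmentationDataset, batch_size: int = 8) -> float:
    """Mean Dice of the network over a dataset split."""
    scores = []
    for xb, yb in ds.batches(batch_size):
        pred = net.forward(xb, train=False).argmax(axis=1)
        for p, g in zip(pred, yb):
            scores.append(image_metrics(p.astype(np.uint8), g.astype(np.uint8))["dice"])
    return float(np.mean(scores))


def train(net: MDWCNet, data_root, cfg: TrainConfig, out_dir,
          target_size: int | None = None) -> tuple[MDWCNet, list[dict]]:
    """Run the full optimisation protocol on the train/val splits.

    Returns the network (weights of the final epoch in place) and the
    per-epoch history; the best-validation-Dice checkpoint and a history CSV
    are written under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_ds = SegmentationDataset(data_root, "train", target_size)
    val_ds = SegmentationDataset(data_root, "val", target_size)
    if len(train_ds) == 0:
        raise InvalidInputError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(net.params(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    history: list[dict] = []
    best_dice = -1.0
    ckpt = out_dir / "checkpoint.npz"
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(epoch, cfg)
        t0 = time.time()
        losses = []
        for xb, yb in train_ds.batches(cfg.batch_size, rng=rng, augment=True,
                                       flip_prob=cfg.flip_prob):
            logits = net.forward(xb, train=True)
            loss, grad = ce_loss(logits, yb)
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_losses, val_scores = [], []
        for xb, yb in val_ds.batches(cfg.batch_size):
            logits = net.forward(xb, train=False)
            val_losses.append(ce_loss(logits, yb)[0])
            for p, g in zip(logits.argmax(axis=1), yb):
                val_scores.append(image_metrics(p.astype(np.uint8), g.astype(np.uint8))["dice"])
        row = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "val_loss": float(np.mean(val_losses)),
            "val_dice": float(np.mean(val_scores)),
        }
        history.append(row)
        if row["val_dice"] > best_dice:
            best_dice = row["val_dice"]
            save_checkpoint(net, ckpt)
        logger.info(
            "epoch %d/%d lr %.2e train %.4f val %.4f dice %.4f (%.1fs)",
            epoch + 1, cfg.epochs, row["lr"], row["train_loss"],
            row["val_loss"], row["val_dice"], time.time() - t0,
        )
    with open(out_dir / "history.csv", "w", newline="") as f:
        wr = csv.DictWriter(f, fieldnames=["epoch", "lr", "train_loss", "val_loss", "val_dice"])
        wr.writeheader()
        wr.writerows(history)
    return net, history


def overfit_single_batch(net: MDWCNet, xb: np.ndarray, yb: np.ndarray,
                         steps: int = 200, lr: float = 1e-3,
                         momentum: float = 0.9) -> list[float]:
    """Drive one batch to near-zero loss; a training-loop sanity probe."""
    opt = nn.SGD(net.params(), lr=lr, momentum=momentum)
    losses = []
    for _ in range(steps):
        logits = net.forward(xb, train=True)
        loss, grad = ce_loss(logits, yb)
        opt.zero_grad()
        net.backward(grad)
        opt.step()
        losses.append(loss)
    return losses
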