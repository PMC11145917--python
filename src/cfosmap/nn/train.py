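"""Training loop, loss, optimiser and checkpointing for the segmenter.

The loss is voxel cross-entropy plus soft Dice with equal weights; the
optimiser is AdamW.  Per-patch min-max normalisation is applied to images
before the forward pass.  All randomness (train/validation split, batch
order) comes from one seed, so a fixed seed reproduces the loss trajectory
on a single thread.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..config import HybridSwinConfig
from .autodiff import Tensor
from .swin import HybridSwinUNet3D, build_model, normalize_patch

__all__ = [
    "TrainReport",
    "AdamW",
    "segmentation_loss",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
]


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


def segmentation_loss(
    probs: Tensor, target: np.ndarray, smooth: float = 1.0, max_pos_weight: float = 100.0
) -> Tensor:
    """Class-balanced cross-entropy + soft Dice (equal weights).

    ``probs`` is (B, D, H, W, 2) softmax output, ``target`` a binary array of
    the spatial shape.  Foreground voxels are rare (sparse spots), so the CE
    term weights them by the batch background/foreground ratio (capped);
    without the reweighting the all-background solution is a strong local
    optimum.  The Dice term is smoothed so patches without any foreground
    stay well defined (the CE term then dominates).
    """
    y = np.asarray(target, dtype=np.float32)
    p1 = probs[..., 1]
    p_true = p1 * y + (p1 * (-1.0) + 1.0) * (1.0 - y)
    n_pos = float(y.sum())
    if 0 < n_pos < y.size:
        w_pos = min(max_pos_weight, (y.size - n_pos) / n_pos)
        w = 1.0 + (w_pos - 1.0) * y
        ce = -(((p_true + 1e-7).log() * w).sum() / float(w.sum()))
    else:
        ce = -((p_true + 1e-7).log().mean())
    inter = (p1 * y).sum()
    dice = (inter * 2.0 + smooth) / (p1.sum() + float(y.sum()) + smooth)
    return ce + (1.0 - dice)


@dataclass
class TrainReport:
    epoch_loss: list[float]
    val_dice: list[float]
    best_epoch: int
    seed: int
    hyper: dict = field(default_factory=dict)

    @property
    def best_val_dice(self) -> float:
        return self.val_dice[self.best_epoch]


def _micro_dice(model: HybridSwinUNet3D, images: np.ndarray, masks: np.ndarray, batch: int) -> float:
    tp = fp = fn = 0
    for i in range(0, len(images), batch):
        probs = model.forward_batch(images[i:i + batch]).data
        pred = probs[..., 1] > probs[..., 0]
        gt = masks[i:i + batch].astype(bool)
        tp += int(np.count_nonzero(pred & gt))
        fp += int(np.count_nonzero(pred & ~gt))
        fn += int(np.count_nonzero(~pred & gt))
    if tp + fp + fn == 0:
        return 1.0
    return 2 * tp / (2 * tp + fp + fn)


def train_model(
    model: HybridSwinUNet3D,
    pairs: list,
    epochs: int = 20,
    lr: float = 3e-3,
    batch_size: int = 8,
    seed: int = 0,
    val_frac: float = 0.2,
    lr_schedule: str = "cosine",
) -> TrainReport:
    """Train on image/mask patch pairs with a held-out validation split.

    The split is by patch index (disjoint), the validation Dice (micro over
    all validation voxels, argmax segmentation) is computed each epoch, and
    the best-epoch weights are restored into the model before returning.
    ``lr_schedule`` is "cosine" (decay to lr/20 over the run, the default)
    or "constant".
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    rng = np.random.default_rng(seed)
    images = np.stack([normalize_patch(p.image) for p in pairs])
    masks = np.stack([np.asarray(p.mask, dtype=np.uint8) for p in pairs])
    if masks.sum() == 0:
        warnings.warn("all training masks are empty; the Dice term is vacuous")

    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(val_frac * len(pairs))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("validation split leaves no training patches")

    opt = AdamW(model.parameters(), lr=lr)
    epoch_loss: list[float] = []
    val_dice: list[float] = []
    best = (-1.0, None, -1)
    for epoch in range(epochs):
        if lr_schedule == "cosine":
            # short warmup, then cosine decay to lr/20
            if epoch == 0 and epochs > 1:
                opt.lr = 0.3 * lr
            else:
                frac = epoch / max(epochs - 1, 1)
                opt.lr = lr * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))
        # anneal the foreground CE weight: a large weight early pulls the
        # model off the all-background optimum; a small weight late puts the
        # argmax decision boundary near the 50% posterior
        frac = epoch / max(epochs - 1, 1)
        pos_weight = float(100.0 ** (1 - frac))  # 100 -> 1 geometric anneal
        perm = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(perm), batch_size):
            idx = perm[i:i + batch_size]
            probs = model.forward_batch(images[idx])
            loss = segmentation_loss(probs, masks[idx], max_pos_weight=pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss.append(float(np.mean(losses)))
        d = _micro_dice(model, images[val_idx], masks[val_idx], batch_size)
        val_dice.append(d)
        if d > best[0]:
            best = (d, model.state_dict(), epoch)
    if best[1] is not None:
        model.load_state_dict(best[1])
    return TrainReport(
        epoch_loss=epoch_loss,
        val_dice=val_dice,
        best_epoch=best[2],
        seed=seed,
        hyper={"epochs": epochs, "lr": lr, "batch_size": batch_size, "val_frac": val_frac,
               "n_train": int(len(train_idx)), "n_val": int(len(val_idx))},
    )


def save_checkpoint(model: HybridSwinUNet3D, path: str | os.PathLike) -> None:
    """Weights + full hyperparameter config + seed in one npz archive."""
    import dataclasses

    path = os.fspath(path)
    meta = json.dumps(dataclasses.asdict(model.cfg))
    state = model.state_dict()
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | os.PathLike) -> HybridSwinUNet3D:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"model checkpoint not found: {path}")
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__config__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    cfg = HybridSwinConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in meta.items()})
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
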