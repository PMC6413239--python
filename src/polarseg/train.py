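"""Seeded training loop minimising the combined Dice + cross-entropy loss.

The loop is deliberately plain: Adam on mini-batches, a seeded shuffle
split into train/validation, per-epoch history of the loss and its
components, and best-validation-loss checkpointing.  Everything stochastic
(split, batch order, weight init if the caller builds the net from the
same seed) derives from explicit seeds, so two runs with identical
configuration produce identical histories on the same machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import losses, nn
from .io import DatasetManifest, LabelMask, read_image, read_mask
from .model import SegmentationNetwork, load_checkpoint, save_checkpoint

__all__ = ["TrainConfig", "TrainHistory", "train", "split_manifest", "load_checkpoint"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int
    batch_size: int = 8
    learning_rate: float = 2e-3
    beta: float = losses.DEFAULT_BETA
    seed: int = 0
    validation_fraction: float = 0.2
    checkpoint_dir: str | Path | None = None
    #: "constant" or "cosine" (cosine anneals the lr to ~0 over the epochs,
    #: which sharpens the late epochs of a short fixed-budget run)
    lr_schedule: str = "cosine"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def split_manifest(
    manifest: DatasetManifest, validation_fraction: float, seed: int
) -> tuple[list[int], list[int]]:
    """Seeded shuffle split of manifest indices into (train, validation).

    The two index lists are disjoint and cover the manifest exactly.
    """
    n = len(manifest)
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(round(n * validation_fraction))
    if n_val >= n:
        n_val = n - 1
    val_idx = sorted(int(i) for i in order[:n_val])
    train_idx = sorted(int(i) for i in order[n_val:])
    assert not set(train_idx) & set(val_idx)
    return train_idx, val_idx


def _load_arrays(manifest: DatasetManifest) -> tuple[np.ndarray, np.ndarray]:
    imgs, masks = [], []
    shape = None
    for entry in manifest.entries:
        img = read_image(manifest.image_path(entry))
        mp = manifest.mask_path(entry)
        mask = read_mask(mp) if mp is not None else LabelMask(np.zeros(img.shape, dtype=np.uint8))
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValueError(f"all images must share one size; got {img.shape} after {shape}")
        imgs.append(img.pixels)
        masks.append(mask.pixels)
    return (
        np.asarray(imgs, dtype=np.float32)[..., None],
        np.asarray(masks, dtype=np.float32)[..., None],
    )


def _eval_loss(net: SegmentationNetwork, x: np.ndarray, y: np.ndarray, beta: float, batch: int) -> losses.LossValue:
    net.eval()
    vals, dices, cates = [], [], []
    for s in range(0, len(x), batch):
        pred = net.forward(x[s : s + batch])
        lv = losses.batch_total_loss(pred, y[s : s + batch], beta)
        w = len(x[s : s + batch])
        vals.append(lv.value * w)
        dices.append(lv.dice * w)
        cates.append(lv.cate * w)
    n = len(x)
    return losses.LossValue(sum(vals) / n, sum(dices) / n, sum(cates) / n, beta)


def train(
    net: SegmentationNetwork, manifest: DatasetManifest, cfg: TrainConfig
) -> tuple[SegmentationNetwork, TrainHistory]:
    """Train ``net`` on a manifest; returns the best-validation checkpoint.

    Raises on an empty manifest, and aborts with a diagnostic naming the
    epoch and batch if the loss goes non-finite.
    """
    if len(manifest) == 0:
        raise ValueError("training manifest is empty")
    x, y = _load_arrays(manifest)
    train_idx, val_idx = split_manifest(manifest, cfg.validation_fraction, cfg.seed)
    if not val_idx:  # tiny datasets: validate on the training set
        val_idx = train_idx
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    rng = np.random.default_rng(cfg.seed + 1)
    optimizer = nn.Adam(net.parameters(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None

    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            optimizer.lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
        net.train(True)
        order = rng.permutation(len(xt))
        epoch_vals, epoch_dices, epoch_cates, weights = [], [], [], []
        for bi, s in enumerate(range(0, len(xt), cfg.batch_size)):
            sel = order[s : s + cfg.batch_size]
            pred = net.forward(xt[sel])
            lv = losses.batch_total_loss(pred, yt[sel], cfg.beta)
            if not np.isfinite(lv.value):
                raise RuntimeError(
                    f"non-finite loss {lv.value} at epoch {epoch}, batch {bi}"
                )
            grad = losses.batch_total_loss_grad(pred, yt[sel], cfg.beta).astype(np.float32)
            net.zero_grad()
            net.backward(grad)
            optimizer.step()
            epoch_vals.append(lv.value * len(sel))
            epoch_dices.append(lv.dice * len(sel))
            epoch_cates.append(lv.cate * len(sel))
            weights.append(len(sel))
        ntr = sum(weights)
        val = _eval_loss(net, xv, yv, cfg.beta, cfg.batch_size)
        history.append(
            epoch=epoch,
            train_loss=sum(epoch_vals) / ntr,
            val_loss=val.value,
            dice=sum(epoch_dices) / ntr,
            cate=sum(epoch_cates) / ntr,
        )
        if val.value < best_val:
            best_val = val.value
            best_state = {k: v.copy() for k, v in net.state_arrays().items()}

    if best_state is not None:
        net.load_state_arrays(best_state)
    net.eval()

    if cfg.checkpoint_dir is not None:
        ckpt_dir = Path(cfg.checkpoint_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(net, ckpt_dir / "best")
        history.save_csv(ckpt_dir / "history.csv")
    return net, history
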