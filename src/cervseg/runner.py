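"""Training and evaluation orchestration.

The published training strategy — Adam, initial learning rate 1e-4, batch
size 16, up to 300 epochs, early stopping and reduce-on-plateau learning
rate scheduling, combined Dice+Tversky loss, real-time augmentation — is
the configuration default. A "desk-scale" recipe (64x64 phantoms, a narrow
model, 30 epochs, batch 8) exercises the identical code path at a size a
single CPU handles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import metrics as M
from .annotations import BinaryMask
from .datapipe import AugmentationPolicy, DatasetManifest, SamplePair, augment_pair
from .losses import LossConfig, combined_loss
from .network import (DualEncoderSegNet, ModelConfig, assemble_ablation,
                      assemble_model, load_checkpoint, save_checkpoint)
from .nn import Adam, Tensor, no_grad

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-4
    early_stopping_patience: int = 25
    lr_plateau_factor: float = 0.5
    lr_plateau_patience: int = 10
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    freeze_backbones: bool = False
    online_augmentation: bool = True
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1, batch_size >= 1, learning_rate > 0 required")

    @classmethod
    def desk(cls, seed: int = 0) -> "TrainConfig":
        """CPU-sized recipe: 64x64 inputs, narrow model, 30 epochs, batch 8."""
        return cls(epochs=30, batch_size=8, learning_rate=3e-3,
                   model=ModelConfig.desk(), seed=seed,
                   augmentation=AugmentationPolicy(rotation_limit=15.0,
                                                   elastic_alpha=0.0,
                                                   brightness_limit=0.1,
                                                   contrast_limit=0.1))


@dataclass
class RunLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    checkpoint_path: str = ""
    wall_time_s: float = 0.0
    stopped_early: bool = False

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _manifest_arrays(manifest: DatasetManifest, size: int):
    images, masks = [], []
    for i in range(len(manifest)):
        pair = manifest.load_pair(i, size=size)
        images.append(pair.image)
        masks.append(pair.mask.data)
    return np.stack(images), np.stack(masks)


def _soft_dice(y: np.ndarray, p: np.ndarray) -> float:
    inter = float((y * p).sum())
    denom = float(y.sum() + p.sum())
    return 2.0 * inter / denom if denom > 0 else 1.0


class Trainer:
    """Mini-batch gradient training with early stopping and LR scheduling."""

    def __init__(self, config: TrainConfig, checkpoint_path):
        self.config = config
        self.checkpoint_path = Path(checkpoint_path)

    def _build(self) -> DualEncoderSegNet:
        if self.config.model.ablation_mode:
            return assemble_ablation(self.config.model, seed=self.config.seed)
        return assemble_model(self.config.model, seed=self.config.seed)

    def fit(self, images, masks, val_images, val_masks) -> tuple[DualEncoderSegNet, RunLog]:
        cfg = self.config
        t0 = time.time()
        rng = np.random.default_rng(cfg.seed)
        model = self._build()
        frozen = set()
        if cfg.freeze_backbones:
            for name, _ in model.resnet.named_parameters("resnet."):
                frozen.add(name)
            if model.mobilenet is not None:
                for name, _ in model.mobilenet.named_parameters("mobilenet."):
                    frozen.add(name)
        trainable = [p for name, p in model.named_parameters() if name not in frozen]
        optimizer = Adam(trainable, lr=cfg.learning_rate)
        log = RunLog()
        best_state = None
        since_best = 0
        since_lr_drop = 0
        n = len(images)
        for epoch in range(cfg.epochs):
            model.train()
            order = rng.permutation(n)
            losses, dices = [], []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = self._batch(images[idx], masks[idx], rng)
                optimizer.zero_grad()
                out = model(xb)
                loss = combined_loss(yb[:, None], out, cfg.loss)
                value = loss.item()
                if not np.isfinite(value):
                    raise FloatingPointError(
                        f"NaN/Inf loss at epoch {epoch}: lr={optimizer.lr:.2e}, "
                        f"batch mean={xb.mean():.3f}, std={xb.std():.3f}")
                loss.backward()
                optimizer.step()
                losses.append(value)
                dices.append(_soft_dice(yb[:, None], out.data))
            val_loss, val_dice = self.validate(model, val_images, val_masks)
            log.train_loss.append(float(np.mean(losses)))
            log.train_dice.append(float(np.mean(dices)))
            log.val_loss.append(val_loss)
            log.val_dice.append(val_dice)
            log.lr_history.append(optimizer.lr)
            logger.info("epoch %3d loss %.4f dice %.3f | val loss %.4f dice %.3f",
                        epoch, log.train_loss[-1], log.train_dice[-1],
                        val_loss, val_dice)
            if val_loss < log.best_val_loss:
                log.best_val_loss = val_loss
                log.best_epoch = epoch
                best_state = model.state_dict()
                since_best = since_lr_drop = 0
            else:
                since_best += 1
                since_lr_drop += 1
                if since_lr_drop >= cfg.lr_plateau_patience:
                    optimizer.lr *= cfg.lr_plateau_factor
                    since_lr_drop = 0
                    logger.info("reducing learning rate to %.2e", optimizer.lr)
                if since_best >= cfg.early_stopping_patience:
                    log.stopped_early = True
                    logger.info("early stopping at epoch %d", epoch)
                    break
        if best_state is not None:
            model.load_state_dict(best_state)
        save_checkpoint(model, self.checkpoint_path)
        log.checkpoint_path = str(self.checkpoint_path)
        log.wall_time_s = time.time() - t0
        return model, log

    def _batch(self, images, masks, rng):
        cfg = self.config
        if cfg.online_augmentation and not cfg.augmentation.is_identity():
            aug_i, aug_m = [], []
            for img, msk in zip(images, masks):
                pair = SamplePair(image=img, mask=BinaryMask(msk))
                aug = augment_pair(pair, cfg.augmentation, rng)
                aug_i.append(aug.image)
                aug_m.append(aug.mask.data)
            images, masks = np.stack(aug_i), np.stack(aug_m)
        xb = images.astype(np.float32).transpose(0, 3, 1, 2)
        yb = masks.astype(np.float32)
        return xb, yb

    @staticmethod
    def validate(model, images, masks) -> tuple[float, float]:
        model.eval()
        with no_grad():
            out = []
            for i in range(0, len(images), 8):
                xb = images[i:i + 8].astype(np.float32).transpose(0, 3, 1, 2)
                out.append(model(Tensor(xb)).data)
            pred = np.concatenate(out, axis=0)
        y = masks.astype(np.float64)[:, None]
        return float(combined_loss(y, pred.astype(np.float64))), _soft_dice(y, pred)


def train(manifest_train: DatasetManifest, manifest_val: DatasetManifest,
          config: TrainConfig, checkpoint_path="checkpoint.npz",
          ) -> tuple[DualEncoderSegNet, RunLog]:
    """Train from manifests on disk (loads everything into memory)."""
    if not len(manifest_train) or not len(manifest_val):
        raise ValueError("training and validation manifests must be non-empty")
    size = config.model.input_size
    xtr, ytr = _manifest_arrays(manifest_train, size)
    xva, yva = _manifest_arrays(manifest_val, size)
    return Trainer(config, checkpoint_path).fit(xtr, ytr, xva, yva)


def train_arrays(images, masks, val_images, val_masks, config: TrainConfig,
                 checkpoint_path="checkpoint.npz") -> tuple[DualEncoderSegNet, RunLog]:
    """Train directly from in-memory arrays (phantom workflows)."""
    return Trainer(config, checkpoint_path).fit(
        np.asarray(images), np.asarray(masks),
        np.asarray(val_images), np.asarray(val_masks))


def evaluate(manifest_test: DatasetManifest, checkpoint, threshold: float = 0.5
             ) -> M.MetricReport:
    """Score a checkpoint on a test manifest with the full metric suite."""
    model = checkpoint if isinstance(checkpoint, DualEncoderSegNet) \
        else load_checkpoint(checkpoint)
    size = model.config.input_size
    images, masks = _manifest_arrays(manifest_test, size)
    return evaluate_arrays(model, images, masks, threshold)


def evaluate_arrays(model: DualEncoderSegNet, images, masks,
                    threshold: float = 0.5) -> M.MetricReport:
    prob = model.predict(np.asarray(images))
    pred = (prob >= threshold).astype(np.uint8)
    truth = np.asarray(masks).astype(np.uint8)
    pairs = [(truth[i], pred[i]) for i in range(len(truth))]
    return M.evaluate_dataset(pairs)
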