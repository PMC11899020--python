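"""Overlap-based segmentation losses.

The training objective is the sum of Dice loss and Tversky loss:

    DiceLoss    = 1 - (2 Σ y·ŷ + ε) / (Σ y + Σ ŷ + ε)
    TverskyLoss = 1 - (Σ y·ŷ + ε) / (Σ y·ŷ + α Σ y(1-ŷ) + β Σ (1-y)ŷ + ε)
    CombinedLoss = DiceLoss + TverskyLoss

with ε a smoothing constant. α weights false negatives and β false
positives; the defaults emphasize false negatives (α = 0.7, β = 0.3),
appropriate when lesions are small relative to the background. Sums run
over all pixels of the batch, which keeps the estimate stable when
individual images contain tiny foreground regions. At α = β = 0.5 the
Tversky index reduces to the Dice coefficient, so the two losses coincide
on binary inputs.

All three losses accept either plain numpy arrays (returning floats) or
autodiff tensors (returning a differentiable scalar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor


@dataclass
class LossConfig:
    alpha: float = 0.7       # false-negative weight
    beta: float = 0.3        # false-positive weight
    epsilon: float = 1e-6    # smoothing constant
    include_bce: bool = False

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")


def _shape_of(x):
    return x.data.shape if isinstance(x, Tensor) else np.shape(x)


def _check_shapes(y, y_hat):
    ys, ps = _shape_of(y), _shape_of(y_hat)
    if tuple(ys) != tuple(ps):
        raise ValueError(f"shape mismatch: truth {ys} vs prediction {ps}")


def dice_loss(y, y_hat, epsilon: float = 1e-6):
    """1 - soft Dice coefficient over all pixels."""
    _check_shapes(y, y_hat)
    if isinstance(y_hat, Tensor):
        y_t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=y_hat.data.dtype))
        inter = (y_t * y_hat).sum()
        denom = y_t.sum() + y_hat.sum()
        return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    inter = float((y * y_hat).sum())
    return 1.0 - (2.0 * inter + epsilon) / (float(y.sum()) + float(y_hat.sum()) + epsilon)


def tversky_loss(y, y_hat, config: LossConfig | None = None):
    """1 - Tversky index with asymmetric FN/FP weights."""
    config = config or LossConfig()
    _check_shapes(y, y_hat)
    a, b, eps = config.alpha, config.beta, config.epsilon
    if isinstance(y_hat, Tensor):
        y_t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=y_hat.data.dtype))
        tp = (y_t * y_hat).sum()
        fn = (y_t * (1.0 - y_hat)).sum()
        fp = ((1.0 - y_t) * y_hat).sum()
        return 1.0 - (tp + eps) / (tp + a * fn + b * fp + eps)
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    tp = float((y * y_hat).sum())
    fn = float((y * (1.0 - y_hat)).sum())
    fp = float(((1.0 - y) * y_hat).sum())
    return 1.0 - (tp + eps) / (tp + a * fn + b * fp + eps)


def bce_loss(y, y_hat, epsilon: float = 1e-7):
    """Pixel-mean binary cross-entropy (optional add-on, off by default)."""
    _check_shapes(y, y_hat)
    if isinstance(y_hat, Tensor):
        from .nn.tensor import log
        y_t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=y_hat.data.dtype))
        p = y_hat * (1.0 - 2.0 * epsilon) + epsilon  # clamp away from {0,1}
        return -(y_t * log(p) + (1.0 - y_t) * log(1.0 - p)).mean()
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(y_hat, dtype=float), epsilon, 1.0 - epsilon)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def combined_loss(y, y_hat, config: LossConfig | None = None):
    """Dice + Tversky with a shared ε (plus optional BCE when enabled)."""
    config = config or LossConfig()
    total = dice_loss(y, y_hat, config.epsilon) + tversky_loss(y, y_hat, config)
    if config.include_bce:
        total = total + bce_loss(y, y_hat)
    return total
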