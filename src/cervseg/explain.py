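"""Grad-CAM++ explainability for the segmentation network.

For a chosen spatial layer A with channels c, Grad-CAM++ weights each
channel by a spatial average of its positive gradients,

    alpha_c(u,v) = g_c(u,v)^2 / (2 g_c(u,v)^2 + sum_{u,v} A_c g_c^3),
    w_c = sum_{u,v} alpha_c(u,v) * relu(g_c(u,v)),

where g = d(target)/dA. The class-activation map relu(sum_c w_c A_c) is
min-max normalized and bilinearly upsampled to the input size. For a dense
sigmoid output the "class score" is taken as the sum of predicted
probabilities over pixels the model calls foreground (p > 0.5) — the
standard segmentation adaptation of a classifier score.

Heatmaps can be rendered as colormapped overlays and scored against
reference masks with Cohen's kappa after thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .metrics import cohens_kappa
from .nn.tensor import Tensor, constant

logger = logging.getLogger(__name__)


@dataclass
class Heatmap:
    """Normalized class-activation map in [0, 1]."""

    values: np.ndarray
    source_layer: str = ""
    target_description: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("heatmap values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


def normalize_cam(cam: np.ndarray) -> np.ndarray:
    """ReLU then min-max normalize; idempotent; all-zero maps stay zero."""
    cam = np.maximum(np.asarray(cam, dtype=np.float64), 0.0)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def gradcam_pp(model, image, layer_id: str, *, threshold: float = 0.5) -> Heatmap:
    """Grad-CAM++ heatmap of ``layer_id`` for one RGB image.

    ``model`` must be callable on an NCHW batch, returning the sigmoid
    output tensor, and expose ``activation(layer_id)`` afterwards.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3 and image.shape[2] == 3:
        batch = image.transpose(2, 0, 1)[None]
    elif image.ndim == 3 and image.shape[0] == 3:
        batch = image[None]
    else:
        raise ValueError(f"expected an HxWx3 or 3xHxW image, got {image.shape}")
    h, w = batch.shape[2], batch.shape[3]

    was_training = getattr(model, "training", False)
    if hasattr(model, "eval"):
        model.eval()
    out = model(Tensor(batch))
    act = model.activation(layer_id)
    fg = (out.data > threshold).astype(out.data.dtype)
    target = (out * constant(fg)).sum()
    target.backward()
    if hasattr(model, "train"):
        model.train(was_training)

    a = np.asarray(act.data[0], dtype=np.float64)          # C x Ha x Wa
    g = np.asarray(act.grad[0] if act.grad is not None else np.zeros_like(a),
                   dtype=np.float64)
    if not np.any(g):
        logger.warning("all-zero gradients for layer %s; heatmap is empty", layer_id)
        cam = np.zeros(a.shape[1:], dtype=np.float64)
    else:
        g2, g3 = g ** 2, g ** 3
        denom = 2.0 * g2 + (a * g3).sum(axis=(1, 2), keepdims=True)
        alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1, denom), 0.0)
        weights = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2))
        cam = normalize_cam(np.tensordot(weights, a, axes=(0, 0)))
    if cam.shape != (h, w):
        cam = np.clip(_sk_resize(cam, (h, w), order=1, mode="edge",
                                 anti_aliasing=False, preserve_range=True), 0.0, 1.0)
    return Heatmap(values=cam, source_layer=layer_id,
                   target_description=f"sum of sigmoid outputs over p>{threshold}")


def overlay_heatmap(image, heatmap: Heatmap, opacity: float = 0.5,
                    cmap: str = "jet") -> np.ndarray:
    """Blend a colormapped heatmap onto an RGB image in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[:2] != heatmap.values.shape:
        raise ValueError(f"image {image.shape[:2]} and heatmap "
                         f"{heatmap.values.shape} sizes differ")
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must be in [0, 1]")
    colored = colormaps[cmap](heatmap.values)[..., :3]
    return np.clip((1.0 - opacity) * image + opacity * colored, 0.0, 1.0)


def heatmap_agreement_kappa(heatmap: Heatmap, reference, threshold: float = 0.5
                            ) -> float:
    """Cohen's kappa between the thresholded heatmap and a reference mask."""
    from .annotations import BinaryMask
    ref = reference.data if isinstance(reference, BinaryMask) else np.asarray(reference)
    if heatmap.values.shape != ref.shape:
        raise ValueError(f"heatmap {heatmap.values.shape} and reference "
                         f"{ref.shape} sizes differ")
    return cohens_kappa(ref.astype(bool), heatmap.values >= threshold)
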