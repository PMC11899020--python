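"""Segmentation evaluation suite.

All region metrics derive from a (k+1) x (k+1) confusion matrix p, where
p_ij counts pixels of true class i predicted as class j (binary task:
k = 1, classes background/lesion):

    PA    = Σ p_ii / Σ p_ij
    MPA   = mean_i  p_ii / Σ_j p_ij
    MIoU  = mean_i  p_ii / (Σ_j p_ij + Σ_j p_ji - p_ii)
    FWIoU = Σ_i (Σ_j p_ij / Σ p) · p_ii / (Σ_j p_ij + Σ_j p_ji - p_ii)
    Dice  = 2 TP / (2 TP + FP + FN)                (foreground class)

Boundary agreement uses the symmetric Hausdorff distance between the
foreground boundary point sets (Euclidean, in pixels), and rater
agreement uses Cohen's κ = (p_o - p_e) / (1 - p_e).

Dataset-level region metrics pool confusion counts over all images (the
convention behind published comparison tables); Hausdorff and κ average
per image, skipping pairs where the Hausdorff distance is undefined.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .annotations import BinaryMask

logger = logging.getLogger(__name__)


class EmptyMaskError(ValueError):
    """Hausdorff distance is undefined when a mask has no foreground."""


def _mask_array(m) -> np.ndarray:
    arr = m.data if isinstance(m, BinaryMask) else np.asarray(m)
    return arr.astype(bool)


@dataclass
class ConfusionCounts:
    """Pooled pixel confusion matrix; binary by default (k = 1)."""

    p: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), dtype=np.int64))

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=np.int64)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.p < 0).any():
            raise ValueError("confusion counts must be >= 0")

    @property
    def k(self) -> int:
        return self.p.shape[0] - 1

    @property
    def total(self) -> int:
        return int(self.p.sum())


def accumulate_confusion(y, y_hat, running: ConfusionCounts | None = None
                         ) -> ConfusionCounts:
    """Add one truth/prediction mask pair into the running counts."""
    yt, yp = _mask_array(y), _mask_array(y_hat)
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {yp.shape}")
    running = running or ConfusionCounts()
    p = running.p.copy()
    p[0, 0] += int((~yt & ~yp).sum())
    p[0, 1] += int((~yt & yp).sum())
    p[1, 0] += int((yt & ~yp).sum())
    p[1, 1] += int((yt & yp).sum())
    return ConfusionCounts(p)


def _require_total(c: ConfusionCounts):
    if c.total == 0:
        raise ValueError("empty confusion counts")


def pixel_accuracy(c: ConfusionCounts) -> float:
    _require_total(c)
    return float(np.trace(c.p) / c.total)


def _per_class_accuracy(c: ConfusionCounts) -> list[float]:
    out = []
    for i in range(c.k + 1):
        row = c.p[i].sum()
        if row == 0:
            logger.warning("class %d absent from ground truth; excluded from MPA", i)
            continue
        out.append(float(c.p[i, i] / row))
    return out


def mean_pixel_accuracy(c: ConfusionCounts) -> float:
    _require_total(c)
    accs = _per_class_accuracy(c)
    if not accs:
        raise ValueError("no class has ground-truth pixels")
    return float(np.mean(accs))


def _per_class_iou(c: ConfusionCounts) -> list[float | None]:
    ious: list[float | None] = []
    for i in range(c.k + 1):
        union = c.p[i].sum() + c.p[:, i].sum() - c.p[i, i]
        ious.append(None if union == 0 else float(c.p[i, i] / union))
    return ious


def mean_iou(c: ConfusionCounts) -> float:
    _require_total(c)
    ious = [v for v in _per_class_iou(c) if v is not None]
    if not ious:
        raise ValueError("IoU undefined for every class")
    return float(np.mean(ious))


def fw_iou(c: ConfusionCounts) -> float:
    _require_total(c)
    total = c.total
    acc = 0.0
    for i, iou in enumerate(_per_class_iou(c)):
        freq = c.p[i].sum() / total
        if iou is not None:
            acc += freq * iou
    return float(acc)


def dice_coefficient(c: ConfusionCounts) -> float:
    """Foreground Dice, 2TP / (2TP + FP + FN)."""
    tp, fp, fn = int(c.p[1, 1]), int(c.p[0, 1]), int(c.p[1, 0])
    if tp + fp + fn == 0:
        raise ValueError("Dice undefined: no foreground in truth or prediction")
    return 2.0 * tp / (2.0 * tp + fp + fn)


def boundary_pixels(mask) -> np.ndarray:
    """(row, col) coordinates of foreground pixels with a background
    4-neighbor or lying on the image edge."""
    m = _mask_array(mask)
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(m & ~interior)


def hausdorff_distance(a, b) -> float:
    """Symmetric Hausdorff distance between foreground boundaries, px."""
    pa, pb = boundary_pixels(a), boundary_pixels(b)
    if len(pa) == 0 or len(pb) == 0:
        raise EmptyMaskError("Hausdorff distance undefined for empty foreground")
    d_ab = directed_hausdorff(pa.astype(float), pb.astype(float))[0]
    d_ba = directed_hausdorff(pb.astype(float), pa.astype(float))[0]
    return float(max(d_ab, d_ba))


def cohens_kappa(a, b) -> float:
    """Chance-corrected pixel agreement between two binary label maps."""
    ya, yb = _mask_array(a), _mask_array(b)
    if ya.shape != yb.shape:
        raise ValueError(f"shape mismatch: {ya.shape} vs {yb.shape}")
    n = ya.size
    po = float((ya == yb).sum() / n)
    fa, fb = float(ya.sum() / n), float(yb.sum() / n)
    pe = fa * fb + (1.0 - fa) * (1.0 - fb)
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            return 1.0  # both raters constant and identical
        raise ValueError("kappa undefined: chance agreement is 1 but raters differ")
    return (po - pe) / (1.0 - pe)


@dataclass
class MetricReport:
    pa: float
    mpa: float
    miou: float
    fwiou: float
    dice: float
    hausdorff: float | None
    kappa: float
    n_images: int
    n_hausdorff_excluded: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("pa", "mpa", "miou", "fwiou", "dice", "hausdorff", "kappa",
                 "n_images", "n_hausdorff_excluded")}

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "MetricReport":
        return cls(**json.loads(Path(path).read_text()))


def evaluate_dataset(pairs) -> MetricReport:
    """Score (truth, prediction) mask pairs: pooled confusion for the
    region metrics, per-image averages for Hausdorff and κ."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (truth, prediction) pair")
    counts = ConfusionCounts()
    hds, kappas = [], []
    excluded = 0
    for truth, pred in pairs:
        counts = accumulate_confusion(truth, pred, counts)
        kappas.append(cohens_kappa(truth, pred))
        try:
            hds.append(hausdorff_distance(truth, pred))
        except EmptyMaskError:
            excluded += 1
    if excluded:
        logger.warning("Hausdorff undefined for %d/%d pairs (empty foreground)",
                       excluded, len(pairs))
    return MetricReport(
        pa=pixel_accuracy(counts),
        mpa=mean_pixel_accuracy(counts),
        miou=mean_iou(counts),
        fwiou=fw_iou(counts),
        dice=dice_coefficient(counts),
        hausdorff=float(np.mean(hds)) if hds else None,
        kappa=float(np.mean(kappas)),
        n_images=len(pairs),
        n_hausdorff_excluded=excluded,
    )
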