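"""Paired image/mask data handling.

Covers the preprocessing pipeline the segmentation model expects: resizing
to a square input with intensities in [0, 1], backbone-specific channel
standardization, mask-consistent geometric augmentation, offline dataset
expansion that preserves class proportions, stratified train/val/test
splitting, and the class-imbalance statistic reported for the CIN-graded
colposcopy cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .annotations import CLASS_LABELS, BinaryMask, read_mask

logger = logging.getLogger(__name__)

# Per-channel standardization constants on the 0-255 scale, by backbone
# family: the large-scale natural-image statistics conventional for
# resnet-style encoders, and symmetric [-1, 1] scaling conventional for
# mobilenet-style encoders.
STANDARDIZATION = {
    "resnet-branch": (np.array([123.675, 116.28, 103.53]),
                      np.array([58.395, 57.12, 57.375])),
    "mobilenet-branch": (np.array([127.5, 127.5, 127.5]),
                         np.array([127.5, 127.5, 127.5])),
}


@dataclass
class SamplePair:
    """An aligned image/mask pair, the unit flowing through the pipeline."""

    image: np.ndarray          # H x W x 3 float in [0, 1]
    mask: BinaryMask
    class_label: str = "CIN1"
    id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be HxWx3, got {self.image.shape}")
        if self.image.shape[:2] != self.mask.data.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.data.shape} disagree")
        if self.image.min() < -1e-9 or self.image.max() > 1 + 1e-9:
            raise ValueError("image values must lie in [0, 1]")


@dataclass
class AugmentationPolicy:
    """Magnitudes for the transform families used during augmentation."""

    rotation_limit: float = 30.0        # degrees
    flip_horizontal: bool = True
    flip_vertical: bool = True
    brightness_limit: float = 0.2       # fraction of full scale
    contrast_limit: float = 0.2
    elastic_alpha: float = 40.0         # displacement magnitude, px
    elastic_sigma: float = 6.0          # displacement smoothness, px
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_limit", "brightness_limit", "contrast_limit",
                     "elastic_alpha", "elastic_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def is_identity(self) -> bool:
        return (self.rotation_limit == 0 and not self.flip_horizontal
                and not self.flip_vertical and self.brightness_limit == 0
                and self.contrast_limit == 0 and self.elastic_alpha == 0)


@dataclass
class SplitSpec:
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    stratify_by_class: bool = True

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {self.ratios}")


@dataclass
class DatasetManifest:
    """Records of (id, image_path, mask_path, class_label)."""

    records: list[dict] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    @property
    def counts_per_class(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_LABELS}
        for rec in self.records:
            counts[rec["class_label"]] = counts.get(rec["class_label"], 0) + 1
        return counts

    def ids(self) -> set[str]:
        return {rec["id"] for rec in self.records}

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        df = pd.read_csv(path)
        required = {"id", "image_path", "mask_path", "class_label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
        return cls(records=df[sorted(required)].to_dict("records"))

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.records,
                     columns=["id", "image_path", "mask_path", "class_label"]
                     ).to_csv(path, index=False)

    def load_pair(self, index: int, size: int | None = None) -> SamplePair:
        rec = self.records[index]
        image = np.asarray(Image.open(rec["image_path"]).convert("RGB"))
        mask = read_mask(rec["mask_path"])
        if size is not None:
            return resize_normalize(image, mask.data, size,
                                    class_label=rec["class_label"], id=rec["id"])
        return SamplePair(image=image / 255.0, mask=mask,
                          class_label=rec["class_label"], id=rec["id"])


def resize_normalize(image, mask, size: int, *, class_label: str = "CIN1",
                     id: str = "") -> SamplePair:
    """Resize both members to size x size; image to [0, 1] floats.

    The image is interpolated bilinearly; the mask uses nearest-neighbor
    and is re-binarized so no interpolation gray values survive.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.size == 0 or mask.size == 0 or 0 in image.shape or 0 in mask.shape:
        raise ValueError("empty image or mask")
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.max() > 1.0:
        image = image / 255.0
    image = _sk_resize(image, (size, size), order=1, mode="reflect",
                       anti_aliasing=False, preserve_range=True)
    image = np.clip(image, 0.0, 1.0)
    mask_bin = (mask.astype(np.float64) > (127 if mask.max() > 1 else 0.5))
    mask_rs = _sk_resize(mask_bin.astype(np.float64), (size, size), order=0,
                         mode="edge", anti_aliasing=False, preserve_range=True)
    mask_out = BinaryMask((mask_rs > 0.5).astype(np.uint8))
    return SamplePair(image=image, mask=mask_out, class_label=class_label, id=id)


def backbone_standardize(pair_or_image, backbone_id: str) -> np.ndarray:
    """Per-channel (image*255 - mean_c) / std_c for the named backbone family."""
    if backbone_id not in STANDARDIZATION:
        raise KeyError(f"unknown backbone_id {backbone_id!r}; "
                       f"expected one of {sorted(STANDARDIZATION)}")
    image = pair_or_image.image if isinstance(pair_or_image, SamplePair) else pair_or_image
    mean, std = STANDARDIZATION[backbone_id]
    return (np.asarray(image, dtype=np.float64) * 255.0 - mean) / std


def backbone_destandardize(array: np.ndarray, backbone_id: str) -> np.ndarray:
    """Inverse of :func:`backbone_standardize` (back to [0, 1])."""
    mean, std = STANDARDIZATION[backbone_id]
    return (np.asarray(array) * std + mean) / 255.0


def _elastic_fields(shape, alpha: float, sigma: float, rng: np.random.Generator):
    dr = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    dc = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma) * alpha
    return dr, dc


def augment_pair(pair: SamplePair, policy: AugmentationPolicy,
                 rng: np.random.Generator | None = None) -> SamplePair:
    """Apply one random policy draw; geometry hits image and mask alike,
    photometry (brightness/contrast) hits the image only."""
    rng = rng if rng is not None else np.random.default_rng(policy.seed)
    image = pair.image.copy()
    mask = pair.mask.data.astype(np.float64)

    if policy.flip_horizontal and rng.random() < 0.5:
        image, mask = image[:, ::-1], mask[:, ::-1]
    if policy.flip_vertical and rng.random() < 0.5:
        image, mask = image[::-1], mask[::-1]
    if policy.rotation_limit > 0:
        angle = rng.uniform(-policy.rotation_limit, policy.rotation_limit)
        image = ndimage.rotate(image, angle, axes=(1, 0), reshape=False,
                               order=1, mode="constant", cval=0.0)
        mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False,
                              order=0, mode="constant", cval=0.0)
    if policy.elastic_alpha > 0:
        dr, dc = _elastic_fields(mask.shape, policy.elastic_alpha,
                                 policy.elastic_sigma, rng)
        rows, cols = np.meshgrid(np.arange(mask.shape[0]),
                                 np.arange(mask.shape[1]), indexing="ij")
        coords = [rows + dr, cols + dc]
        image = np.stack([ndimage.map_coordinates(image[..., c], coords, order=1,
                                                  mode="reflect")
                          for c in range(3)], axis=-1)
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="reflect")
    if policy.brightness_limit > 0:
        image = image + rng.uniform(-policy.brightness_limit, policy.brightness_limit)
    if policy.contrast_limit > 0:
        factor = 1.0 + rng.uniform(-policy.contrast_limit, policy.contrast_limit)
        image = (image - 0.5) * factor + 0.5

    image = np.clip(image, 0.0, 1.0)
    mask_out = BinaryMask((mask > 0.5).astype(np.uint8))
    return SamplePair(image=np.ascontiguousarray(image), mask=mask_out,
                      class_label=pair.class_label, id=pair.id)


def largest_remainder_allocation(counts, total: int) -> list[int]:
    """Integer allocation of ``total`` proportional to ``counts`` with the
    largest-remainder correction so the allocation sums exactly."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("counts must sum to > 0")
    quotas = counts * total / counts.sum()
    alloc = np.floor(quotas).astype(int)
    remainder = total - alloc.sum()
    order = np.argsort(-(quotas - alloc), kind="stable")
    alloc[order[:remainder]] += 1
    return alloc.tolist()


def expand_dataset(manifest: DatasetManifest, target_total: int,
                   policy: AugmentationPolicy, seed: int, out_dir,
                   *, size: int | None = None) -> DatasetManifest:
    """Grow the dataset to ``target_total`` by appending augmented copies,
    preserving class proportions via largest-remainder rounding. Originals
    are retained; augmented records carry provenance ids."""
    counts = manifest.counts_per_class
    classes = [c for c in CLASS_LABELS if counts.get(c, 0) > 0]
    if len(classes) < len(CLASS_LABELS):
        raise ValueError(f"every class needs at least one sample, got {counts}")
    if target_total < len(manifest):
        raise ValueError(f"target_total {target_total} < current total {len(manifest)}")
    targets = dict(zip(classes, largest_remainder_allocation(
        [counts[c] for c in classes], target_total)))

    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    new_records = list(manifest.records)
    by_class = {c: [r for r in manifest.records if r["class_label"] == c]
                for c in classes}
    for cls in classes:
        need = targets[cls] - counts[cls]
        if need < 0:
            raise ValueError(f"class {cls} already exceeds its target share")
        for k in range(need):
            src = by_class[cls][int(rng.integers(len(by_class[cls])))]
            pair = _load_record_pair(src, size)
            aug = augment_pair(pair, policy, rng)
            aug_id = f"{src['id']}-aug{k:04d}"
            img_path = out_dir / "images" / f"{aug_id}.png"
            msk_path = out_dir / "masks" / f"{aug_id}.png"
            img_path.parent.mkdir(parents=True, exist_ok=True)
            msk_path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray((aug.image * 255).round().astype(np.uint8)).save(img_path)
            Image.fromarray(aug.mask.data * np.uint8(255), mode="L").save(msk_path)
            new_records.append({"id": aug_id, "image_path": str(img_path),
                                "mask_path": str(msk_path), "class_label": cls})
    return DatasetManifest(records=new_records)


def _load_record_pair(rec: dict, size: int | None) -> SamplePair:
    image = np.asarray(Image.open(rec["image_path"]).convert("RGB"))
    mask = read_mask(rec["mask_path"])
    if size is not None:
        return resize_normalize(image, mask.data, size,
                                class_label=rec["class_label"], id=rec["id"])
    return SamplePair(image=image / 255.0, mask=mask,
                      class_label=rec["class_label"], id=rec["id"])


def expanded_class_targets(counts, target_total: int) -> list[int]:
    """Per-class counts after proportional expansion (largest remainder)."""
    return largest_remainder_allocation(counts, target_total)


def stratified_split(manifest: DatasetManifest, spec: SplitSpec
                     ) -> tuple[DatasetManifest, DatasetManifest, DatasetManifest]:
    """Disjoint, exhaustive train/val/test partition, deterministic per seed;
    per-class proportions preserved within one sample when stratifying."""
    rng = np.random.default_rng(spec.seed)
    splits: tuple[list, list, list] = ([], [], [])
    groups: list[list[dict]]
    if spec.stratify_by_class:
        groups = [[r for r in manifest.records if r["class_label"] == c]
                  for c in CLASS_LABELS]
        groups = [g for g in groups if g]
    else:
        groups = [list(manifest.records)]
    for group in groups:
        if len(group) < 3:
            logger.warning("class group with %d samples cannot fill all splits",
                           len(group))
        order = rng.permutation(len(group))
        alloc = largest_remainder_allocation(spec.ratios, len(group))
        start = 0
        for split_idx, n in enumerate(alloc):
            for i in order[start:start + n]:
                splits[split_idx].append(group[int(i)])
            start += n
    return tuple(DatasetManifest(records=s) for s in splits)  # type: ignore[return-value]


def class_imbalance_percent(counts) -> float:
    """100 * (max - min) / total — the spread between the largest and
    smallest class share, in percent (reported to 2 decimals)."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("counts must be nonempty with positive total")
    return round(float(100.0 * (counts.max() - counts.min()) / counts.sum()), 2)
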