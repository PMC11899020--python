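"""Phantom colposcopy-like images with exact ground truth.

Each phantom is a dark frame containing a bright pinkish ellipse (the
cervix field) with one or more smooth irregular "acetowhite" blobs inside
it — polygons with radius r(theta) = R (1 + sum_h a_h sin(h theta + phi_h))
over harmonics h = 2..5, sampled at 72 vertices — whose union is the
lesion mask. Lesion area fraction is drawn from a per-class range so CIN
grade correlates with lesion load (CIN1 < CIN2 < CIN3). Gaussian texture
noise and optional small specular highlight discs (never overlapping the
mask) emulate the artifacts real colposcopy frames carry. The generating
polygons are emitted as LabelMe-dialect annotations, so every downstream
module can be exercised without any real data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .annotations import AnnotationSet, BinaryMask, PolygonAnnotation, fill_polygon
from .datapipe import DatasetManifest, SamplePair

logger = logging.getLogger(__name__)

# Invented morphometry: per-class lesion area fraction ranges, chosen to
# give a learnable class-correlated signal with small-lesion pressure.
DEFAULT_AREA_FRACTIONS = {
    "CIN1": (0.02, 0.06),
    "CIN2": (0.06, 0.12),
    "CIN3": (0.12, 0.22),
}
DEFAULT_LESION_COUNTS = {"CIN1": 1, "CIN2": 2, "CIN3": 2}


class GenerationError(RuntimeError):
    pass


@dataclass
class PhantomSpec:
    size: int = 256
    class_label: str = "CIN3"
    lesion_count: int | None = None          # None -> class default
    area_fraction_range: tuple[float, float] | None = None
    lesion_contrast: float = 0.30            # brightness delta of lesions
    noise_sigma: float = 0.03
    specular_artifacts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("size must be >= 32")
        lo, hi = self.resolved_area_range()
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"area fraction range {lo, hi} must satisfy 0<=lo<=hi<=0.5")

    def resolved_area_range(self) -> tuple[float, float]:
        return self.area_fraction_range or DEFAULT_AREA_FRACTIONS[self.class_label]

    def resolved_lesion_count(self) -> int:
        if self.lesion_count is not None:
            return self.lesion_count
        return DEFAULT_LESION_COUNTS[self.class_label]


def _blob_polygon(rng: np.random.Generator, center, radius: float,
                  n_vertices: int = 72) -> np.ndarray:
    """Smooth irregular closed polygon via low-order radial harmonics."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for h in range(2, 6):
        amp = rng.uniform(-0.25, 0.25) / (h - 1)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.sin(h * theta + phase)
    r = np.clip(r, 0.3, None) * radius
    cx, cy = center
    return np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1)


def _inside_ellipse(points: np.ndarray, center, axes, margin: float = 0.0) -> bool:
    dx = (points[:, 0] - center[0]) / (axes[0] - margin)
    dy = (points[:, 1] - center[1]) / (axes[1] - margin)
    return bool(np.all(dx * dx + dy * dy <= 1.0))


def generate_phantom(spec: PhantomSpec) -> tuple[SamplePair, AnnotationSet]:
    """One phantom image, its exact mask, and its generating polygons."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    lo, hi = spec.resolved_area_range()
    n_lesions = spec.resolved_lesion_count()

    # cervix ellipse covering 40-70% of the frame
    ell_frac = rng.uniform(0.40, 0.70)
    aspect = rng.uniform(0.8, 1.25)
    ax = np.sqrt(ell_frac * size * size * aspect / np.pi)
    ay = ax / aspect
    ecx = size / 2 + rng.uniform(-0.03, 0.03) * size
    ecy = size / 2 + rng.uniform(-0.03, 0.03) * size

    mask = np.zeros((size, size), dtype=np.uint8)
    polygons: list[np.ndarray] = []
    if n_lesions > 0:
        target_frac = rng.uniform(lo, hi)
        per_lesion = target_frac / n_lesions
        for _ in range(n_lesions):
            placed = False
            for _attempt in range(200):
                radius = np.sqrt(per_lesion * size * size / np.pi)
                cx = ecx + rng.uniform(-0.6, 0.6) * ax
                cy = ecy + rng.uniform(-0.6, 0.6) * ay
                poly = _blob_polygon(rng, (cx, cy), radius)
                if not _inside_ellipse(poly, (ecx, ecy), (ax, ay), margin=1.0):
                    continue
                polygons.append(poly)
                mask |= fill_polygon(poly, size, size)
                placed = True
                break
            if not placed:
                raise GenerationError(
                    f"could not place lesion inside cervix field (spec={spec})")
        # verify the measured union area fraction; retry with a fresh draw
        frac = mask.sum() / (size * size)
        if not (lo <= frac <= hi):
            for retry in range(50):
                sub = replace(spec, seed=int(rng.integers(2 ** 31)))
                pair, ann = generate_phantom(sub)
                frac = pair.mask.data.sum() / (size * size)
                if lo <= frac <= hi:
                    return (SamplePair(image=pair.image, mask=pair.mask,
                                       class_label=spec.class_label, id=pair.id),
                            ann)
            raise GenerationError(f"area fraction {frac:.3f} outside [{lo}, {hi}]")

    # grayscale-equivalent luminance field, then colorize
    cols, rows = np.meshgrid(np.arange(size), np.arange(size))
    ellipse = (((cols - ecx) / ax) ** 2 + ((rows - ecy) / ay) ** 2) <= 1.0
    lum = np.full((size, size), 0.12)
    lum[ellipse] = 0.55
    lum = ndimage.gaussian_filter(lum, 2.0)
    lum += spec.lesion_contrast * ndimage.gaussian_filter(mask.astype(float), 1.0)

    base_rgb = np.array([1.00, 0.62, 0.66]) + rng.uniform(-0.05, 0.05, 3)
    image = lum[..., None] * base_rgb[None, None, :]
    image += rng.normal(0.0, spec.noise_sigma, image.shape)

    # specular highlights inside the cervix field but never on the mask
    placed_spec = 0
    for _attempt in range(200):
        if placed_spec >= spec.specular_artifacts:
            break
        r = rng.uniform(1.5, 3.5)
        cx = ecx + rng.uniform(-0.7, 0.7) * ax
        cy = ecy + rng.uniform(-0.7, 0.7) * ay
        disc = ((cols - cx) ** 2 + (rows - cy) ** 2) <= r * r
        if not disc.any() or (disc & (mask > 0)).any() or not ellipse[disc].all():
            continue
        image[disc] = 1.0
        placed_spec += 1

    image = np.clip(image, 0.0, 1.0)
    ann = AnnotationSet(
        image_height=size, image_width=size,
        shapes=[PolygonAnnotation(label="lesion",
                                  points=[(float(x), float(y)) for x, y in poly])
                for poly in polygons])
    pair = SamplePair(image=image, mask=BinaryMask(mask),
                      class_label=spec.class_label,
                      id=f"{spec.class_label.lower()}-{spec.seed:08d}")
    return pair, ann


def write_labelme(ann: AnnotationSet, path, image_path: str = "") -> None:
    payload = {
        "version": "5.0.0",
        "imageHeight": ann.image_height,
        "imageWidth": ann.image_width,
        "imagePath": image_path,
        "shapes": [{"label": s.label, "shape_type": "polygon",
                    "points": [[float(x), float(y)] for x, y in s.points]}
                   for s in ann.shapes],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))


def generate_phantom_dataset(n_per_class, out_dir, *, spec_template: PhantomSpec | None = None,
                             seed: int = 0) -> DatasetManifest:
    """Write a phantom dataset (images, masks, annotations, manifest CSV).

    ``n_per_class`` is a mapping or triple of counts for CIN1/CIN2/CIN3.
    """
    out_dir = Path(out_dir)
    template = spec_template or PhantomSpec()
    if not isinstance(n_per_class, dict):
        n_per_class = dict(zip(("CIN1", "CIN2", "CIN3"), n_per_class))
    rng = np.random.default_rng(seed)
    records = []
    for cls, n in n_per_class.items():
        for i in range(n):
            spec = replace(template, class_label=cls,
                           lesion_count=None, area_fraction_range=None,
                           seed=int(rng.integers(2 ** 31)))
            pair, ann = generate_phantom(spec)
            stem = f"{cls.lower()}_{i:04d}"
            img_path = out_dir / "images" / f"{stem}.png"
            msk_path = out_dir / "masks" / f"{stem}.png"
            ann_path = out_dir / "annotations" / f"{stem}.json"
            img_path.parent.mkdir(parents=True, exist_ok=True)
            msk_path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray((pair.image * 255).round().astype(np.uint8)).save(img_path)
            Image.fromarray(pair.mask.data * np.uint8(255), mode="L").save(msk_path)
            write_labelme(ann, ann_path, image_path=str(img_path.name))
            records.append({"id": stem, "image_path": str(img_path),
                            "mask_path": str(msk_path), "class_label": cls})
    manifest = DatasetManifest(records=records)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


def load_phantom_arrays(n_per_class, *, size: int = 64, seed: int = 0,
                        spec_template: PhantomSpec | None = None):
    """In-memory phantom batch: (images (N,H,W,3), masks (N,H,W), labels)."""
    template = spec_template or PhantomSpec()
    if not isinstance(n_per_class, dict):
        n_per_class = dict(zip(("CIN1", "CIN2", "CIN3"), n_per_class))
    rng = np.random.default_rng(seed)
    images, masks, labels = [], [], []
    for cls, n in n_per_class.items():
        for _ in range(n):
            spec = replace(template, size=size, class_label=cls,
                           lesion_count=None, area_fraction_range=None,
                           seed=int(rng.integers(2 ** 31)))
            pair, _ = generate_phantom(spec)
            images.append(pair.image)
            masks.append(pair.mask.data)
            labels.append(cls)
    return np.stack(images), np.stack(masks), labels
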