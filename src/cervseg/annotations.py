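"""Polygon annotations and their conversion to binary lesion masks.

Expert lesion outlines arrive as LabelMe-dialect JSON files: image
dimensions plus a list of labeled polygons given as (x, y) vertex lists
(x = column, y = row, 0-based, origin top-left). The masking procedure
parses each file, fills every polygon on a blank canvas, merges shapes by
union, and writes an 8-bit 0/255 PNG mask.

The pixel-inclusion rule is explicit so it can be checked against an
independent geometric oracle: vertices are rounded to the nearest integer,
and a pixel belongs to the mask iff its center lies inside the polygon
under the even-odd rule or exactly on its boundary. Vertices outside the
frame are handled naturally — only in-frame pixel centers are ever tested,
which is equivalent to clipping the polygon to the frame first.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

CLASS_LABELS = ("CIN1", "CIN2", "CIN3")


class AnnotationError(ValueError):
    """Raised for unreadable or structurally invalid annotation files."""


@dataclass
class PolygonAnnotation:
    """One labeled polygon; the vertex list is implicitly closed."""

    label: str
    points: list[tuple[float, float]]

    def __post_init__(self):
        if len(self.points) < 3:
            raise AnnotationError(
                f"polygon '{self.label}' has {len(self.points)} points; need >= 3")


@dataclass
class AnnotationSet:
    """All polygons annotated on one image."""

    image_height: int
    image_width: int
    shapes: list[PolygonAnnotation] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise AnnotationError(
                f"non-positive image dimensions {self.image_height}x{self.image_width}")


@dataclass
class BinaryMask:
    """H x W array with values in {0, 1}."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.data.shape}")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def foreground_count(self) -> int:
        return int(self.data.sum())


def parse_labelme_file(path) -> AnnotationSet:
    """Parse a LabelMe-dialect JSON annotation file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"cannot parse annotation file {path}: {exc}") from exc
    try:
        height = int(payload["imageHeight"])
        width = int(payload["imageWidth"])
        raw_shapes = payload["shapes"]
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationError(f"malformed annotation file {path}: {exc}") from exc
    shapes = []
    for idx, shape in enumerate(raw_shapes):
        try:
            points = [(float(x), float(y)) for x, y in shape["points"]]
            label = str(shape.get("label", "lesion"))
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"malformed shape {idx} in {path}: {exc}") from exc
        if len(points) < 3:
            raise AnnotationError(
                f"shape {idx} in {path} has {len(points)} points; need >= 3")
        shapes.append(PolygonAnnotation(label=label, points=points))
    return AnnotationSet(image_height=height, image_width=width, shapes=shapes,
                         source_path=str(path))


def _polygon_area(xs: np.ndarray, ys: np.ndarray) -> float:
    """Signed shoelace area."""
    return 0.5 * float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))


def fill_polygon(points, height: int, width: int) -> np.ndarray:
    """Rasterize one polygon: even-odd interior plus boundary pixels.

    Vertices are rounded to the nearest integer grid; a pixel (row r, col c)
    is set iff the point (c, r) is inside the rounded polygon or on one of
    its edges. Fully vectorized over the pixel grid.
    """
    pts = np.asarray(points, dtype=float)
    xs = np.rint(pts[:, 0]).astype(np.int64)
    ys = np.rint(pts[:, 1]).astype(np.int64)
    if abs(_polygon_area(xs.astype(float), ys.astype(float))) == 0.0:
        logger.warning("degenerate polygon with zero area produced no pixels")
        return np.zeros((height, width), dtype=np.uint8)

    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    px = cols.ravel().astype(float)
    py = rows.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    x2s, y2s = np.roll(xs, -1), np.roll(ys, -1)
    for x1, y1, x2, y2 in zip(xs, ys, x2s, y2s):
        # even-odd crossing test, half-open in y to count shared vertices once
        cond = (y1 <= py) != (y2 <= py)
        if np.any(cond):
            x_cross = x1 + (py[cond] - y1) * (x2 - x1) / (y2 - y1)
            hits = np.zeros(px.shape, dtype=bool)
            hits[cond] = px[cond] < x_cross
            inside ^= hits
        # exact on-segment test (integer endpoints, integer query points);
        # zero-length edges (vertices that rounded together) carry no area
        dx, dy = x2 - x1, y2 - y1
        if dx == 0 and dy == 0:
            continue
        cross = (px - x1) * dy - (py - y1) * dx
        dot = (px - x1) * dx + (py - y1) * dy
        seg_len2 = dx * dx + dy * dy
        on_edge |= (cross == 0) & (dot >= 0) & (dot <= seg_len2)
    return (inside | on_edge).reshape(height, width).astype(np.uint8)


def rasterize_annotations(ann: AnnotationSet) -> BinaryMask:
    """Union of all filled polygons, clipped to the image frame."""
    mask = np.zeros((ann.image_height, ann.image_width), dtype=np.uint8)
    for shape in ann.shapes:
        mask |= fill_polygon(shape.points, ann.image_height, ann.image_width)
    return BinaryMask(mask)


def write_mask(mask: BinaryMask, path) -> None:
    """Save as 8-bit grayscale PNG, foreground 255 / background 0."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.data * np.uint8(255), mode="L").save(path)


def read_mask(path) -> BinaryMask:
    """Load a saved mask and re-binarize at 128."""
    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask((arr >= 128).astype(np.uint8))


def batch_convert(annotation_dir, out_dir, *, group_by_class: bool = False,
                  class_labels: dict[str, str] | None = None) -> tuple[int, int]:
    """Convert every ``*.json`` file in a directory to a PNG mask.

    ``class_labels`` maps annotation-file stems to CIN grades; with
    ``group_by_class`` masks are sorted into per-grade subdirectories.
    Returns (written, failed).
    """
    annotation_dir, out_dir = Path(annotation_dir), Path(out_dir)
    written = failed = 0
    for json_path in sorted(annotation_dir.glob("*.json")):
        try:
            ann = parse_labelme_file(json_path)
            mask = rasterize_annotations(ann)
        except AnnotationError as exc:
            logger.warning("skipping %s: %s", json_path, exc)
            failed += 1
            continue
        target_dir = out_dir
        if group_by_class:
            label = (class_labels or {}).get(json_path.stem, "unlabeled")
            target_dir = out_dir / label
        write_mask(mask, target_dir / f"{json_path.stem}.png")
        written += 1
    return written, failed
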