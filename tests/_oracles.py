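"""Independent reference implementations used only to cross-check the
package. These deliberately take the dumbest correct route (per-pixel set
arithmetic, brute-force distance scans, third-party geometry) and never
call the code paths they validate."""

from __future__ import annotations

import numpy as np
import shapely
from scipy.spatial.distance import cdist


def shapely_polygon_mask(points, height: int, width: int) -> np.ndarray:
    """Pixel centers inside or on the boundary of the integer-rounded
    polygon, decided by shapely's covers predicate."""
    pts = np.rint(np.asarray(points, dtype=float))
    poly = shapely.Polygon(pts)
    if poly.area == 0:
        return np.zeros((height, width), dtype=np.uint8)
    cols, rows = np.meshgrid(np.arange(width), np.arange(height))
    centers = shapely.points(cols.ravel().astype(float), rows.ravel().astype(float))
    return shapely.covers(poly, centers).reshape(height, width).astype(np.uint8)


def confusion_from_masks(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """2x2 confusion via explicit set intersections."""
    t, p = truth.astype(bool), pred.astype(bool)
    return np.array([[np.sum(~t & ~p), np.sum(~t & p)],
                     [np.sum(t & ~p), np.sum(t & p)]], dtype=np.int64)


def set_metrics(truth: np.ndarray, pred: np.ndarray) -> dict:
    """PA/MPA/MIoU/FWIoU/Dice straight from mask set operations.

    Classes absent from the ground truth are excluded from MPA; classes
    with empty union are excluded from MIoU; Dice is None when the
    foreground is empty in both masks.
    """
    t, p = truth.astype(bool), pred.astype(bool)
    n = t.size
    out = {"pa": np.sum(t == p) / n}
    accs, ious, freq_iou = [], [], 0.0
    for cls in (False, True):
        tc, pc = t == cls, p == cls
        if tc.sum() > 0:
            accs.append(np.sum(tc & pc) / tc.sum())
        union = np.sum(tc | pc)
        if union > 0:
            iou = np.sum(tc & pc) / union
            ious.append(iou)
            freq_iou += (tc.sum() / n) * iou
    out["mpa"] = float(np.mean(accs))
    out["miou"] = float(np.mean(ious))
    out["fwiou"] = float(freq_iou)
    tp = np.sum(t & p)
    fp = np.sum(~t & p)
    fn = np.sum(t & ~p)
    out["dice"] = None if tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
    return out


def brute_force_hausdorff(pa: np.ndarray, pb: np.ndarray) -> float:
    """max of directed sup-inf Euclidean distances via a full distance matrix."""
    d = cdist(pa.astype(float), pb.astype(float))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def kappa_by_hand(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool).ravel(), b.astype(bool).ravel()
    n = a.size
    po = np.sum(a == b) / n
    pe = (a.sum() / n) * (b.sum() / n) + (1 - a.sum() / n) * (1 - b.sum() / n)
    return (po - pe) / (1 - pe)


def random_star_polygon(rng: np.random.Generator, center, radius: float,
                        n_vertices: int = 12) -> list[tuple[float, float]]:
    """A simple (non-self-intersecting) polygon: random radii on sorted angles."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    r = rng.uniform(0.4, 1.0, n_vertices) * radius
    return [(center[0] + ri * np.cos(ti), center[1] + ri * np.sin(ti))
            for ri, ti in zip(r, theta)]
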