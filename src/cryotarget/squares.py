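"""Square localization in low-magnification grid images.

Segmented square-class pixels are grouped into 4-connected components, each
component is bounded by its convex hull, and a single mesh rotation angle
theta in [0, 90) is found by bounded minimization of the total area of the
per-polygon minimum bounding rectangles aligned at theta:

    theta* = argmin_theta  sum_i A_i(theta)

where A_i(theta) is the area of the axis-aligned bounding box of polygon i's
vertices after rotation by -theta.  The objective has period 90 degrees and
can be multimodal, so the bounded scalar minimizer is restarted from several
brackets.  The rectangles at theta* give tight, angle-aligned crops of every
square.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull, QhullError

from cryotarget.mixture import SegmentationMask
from cryotarget.synthetic import RotatedBox

__all__ = [
    "SquarePolygon",
    "AlignedBoxSet",
    "SquareCrop",
    "extract_polygons",
    "total_aligned_area",
    "find_optimal_angle",
    "crop_squares",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class SquarePolygon:
    """Convex hull of one connected component of square-class pixels."""

    vertices: np.ndarray   # (k, 2) (row, col) in counter-clockwise order
    pixel_count: int


@dataclass
class AlignedBoxSet:
    """Shared rotation angle plus per-polygon aligned bounding rectangles."""

    theta_deg: float
    boxes: list[RotatedBox]        # all carry angle theta_deg
    areas: np.ndarray              # area of each rectangle at theta
    total_area: float


@dataclass
class SquareCrop:
    pixels: np.ndarray
    normalized_pixels: np.ndarray
    source_box: RotatedBox


def extract_polygons(mask: SegmentationMask | np.ndarray,
                     min_pixels: int | None = None) -> list[SquarePolygon]:
    """Convex hull of every 4-connected component of the mask.

    ``min_pixels=None`` drops specks below a quarter of the median component
    size; pass 0 to keep everything.  An empty mask is valid (an image may
    contain no squares) and yields an empty list.
    """
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    labels, n = ndimage.label(m, structure=_FOUR_CONN)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    if min_pixels is None:
        min_pixels = int(0.25 * np.median(sizes))
    polys: list[SquarePolygon] = []
    for lab in range(1, n + 1):
        count = int(sizes[lab - 1])
        if count < min_pixels:
            continue
        pts = np.argwhere(labels == lab).astype(float)
        polys.append(SquarePolygon(vertices=_hull(pts), pixel_count=count))
    return polys


def _hull(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices (CCW); degenerate point sets fall back to their
    extreme points."""
    uniq = np.unique(points, axis=0)
    if len(uniq) < 3:
        return uniq
    try:
        h = ConvexHull(uniq)
        return uniq[h.vertices]
    except QhullError:  # collinear pixels
        order = np.lexsort((uniq[:, 1], uniq[:, 0]))
        return uniq[order][[0, -1]]


def _rot_matrix(theta_deg: float) -> np.ndarray:
    t = math.radians(theta_deg)
    return np.array([[math.cos(t), -math.sin(t)],
                     [math.sin(t), math.cos(t)]])


def _aligned_extents(poly: SquarePolygon, theta_deg: float):
    """Bounding extents of the polygon's vertices in the frame rotated by
    -theta; returns (min_uv, max_uv, rot)."""
    rot = _rot_matrix(theta_deg)
    # row-wise application of R(theta): box-frame coords (height, width axes)
    uv = poly.vertices @ rot.T
    return uv.min(axis=0), uv.max(axis=0), rot


def total_aligned_area(polygons: list[SquarePolygon], theta_deg: float) -> float:
    """Sum of per-polygon aligned-bounding-rectangle areas at ``theta_deg``."""
    if not polygons:
        raise ValueError("need at least one polygon")
    total = 0.0
    for poly in polygons:
        lo, hi, _ = _aligned_extents(poly, theta_deg)
        ext = hi - lo
        total += float(ext[0] * ext[1])
    return total


def _golden_polish(f, a: float, b: float, iters: int = 80) -> float:
    """Golden-section refinement on [a, b]; robust at kink minima."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(iters):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
        if b - a < 1e-13:
            break
    return (a + b) / 2.0


def find_optimal_angle(polygons: list[SquarePolygon],
                       n_starts: int = 8) -> AlignedBoxSet:
    """Minimize total aligned-rectangle area over theta in [0, 90).

    Runs Brent-style bounded minimization from ``n_starts`` evenly spaced
    brackets (the objective is 90-degree periodic and often multimodal) and
    keeps the best minimum.
    """
    if not polygons:
        raise ValueError("need at least one polygon")

    def objective(theta):
        return total_aligned_area(polygons, theta)

    best_theta, best_val = 0.0, objective(0.0)
    edges = np.linspace(0.0, 90.0, n_starts + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-8, "maxiter": 200})
        if res.fun < best_val:
            best_theta, best_val = float(res.x), float(res.fun)
    # golden-section polish: the objective is V-shaped at a lattice angle and
    # Brent's relative-tolerance floor leaves ~1e-7 deg of slack
    theta = _golden_polish(objective, best_theta - 1e-4, best_theta + 1e-4)
    theta %= 90.0

    boxes, areas = [], []
    for poly in polygons:
        lo, hi, rot = _aligned_extents(poly, theta)
        ext = hi - lo
        center_uv = (lo + hi) / 2.0
        center = rot.T @ center_uv          # back to image frame
        boxes.append(RotatedBox(center=(float(center[0]), float(center[1])),
                                width=float(ext[1]), height=float(ext[0]),
                                angle_deg=theta))
        areas.append(float(ext[0] * ext[1]))
    areas = np.asarray(areas)
    return AlignedBoxSet(theta_deg=theta, boxes=boxes, areas=areas,
                         total_area=float(areas.sum()))


def crop_squares(image: np.ndarray, boxset: AlignedBoxSet,
                 pad_fraction: float = 0.05) -> list[SquareCrop]:
    """Resample the image along each aligned rectangle (bilinear).

    Crops are padded by ``pad_fraction`` of the box size on every side and
    clamped to the image.  Normalization uses the mean/sd of all pixels inside
    all boxes of this image (controls for electron dose); a zero-spread image
    normalizes to all zeros via an sd floor.
    """
    H, W = image.shape
    raw_crops: list[np.ndarray | None] = []
    boxes_used: list[RotatedBox] = []
    rot = _rot_matrix(boxset.theta_deg)

    for box in boxset.boxes:
        h = box.height * (1 + 2 * pad_fraction)
        w = box.width * (1 + 2 * pad_fraction)
        nh, nw = max(int(math.ceil(h)), 1), max(int(math.ceil(w)), 1)
        # sample grid in the box frame: nh x nw pixel centers spanning the box
        us = -h / 2.0 + (np.arange(nh) + 0.5) * (h / nh)
        vs = -w / 2.0 + (np.arange(nw) + 0.5) * (w / nw)
        uu, vv = np.meshgrid(us, vs, indexing="ij")
        pts = rot.T @ np.stack([uu.ravel(), vv.ravel()])
        rows = pts[0] + box.center[0]
        cols = pts[1] + box.center[1]
        inside = (rows >= -0.5) & (rows <= H - 0.5) & (cols >= -0.5) & (cols <= W - 0.5)
        if not inside.any():
            warnings.warn("box fully outside image; skipped")
            raw_crops.append(None)
            continue
        crop = ndimage.map_coordinates(image.astype(float),
                                       np.stack([rows, cols]),
                                       order=1, mode="nearest").reshape(nh, nw)
        raw_crops.append(crop)
        boxes_used.append(box)

    pool = np.concatenate([c.ravel() for c in raw_crops if c is not None]) \
        if any(c is not None for c in raw_crops) else np.array([0.0])
    mu = float(pool.mean())
    sd = max(float(pool.std()), 1e-8)

    crops: list[SquareCrop] = []
    for crop, box in zip([c for c in raw_crops if c is not None], boxes_used):
        crops.append(SquareCrop(pixels=crop,
                                normalized_pixels=(crop - mu) / sd,
                                source_box=box))
    return crops
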