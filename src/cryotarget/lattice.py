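"""Hole-center lattice fitting over a probability map.

Foil holes lie on a regular square lattice, so the per-pixel hole-center
probability map O produced by the heatmap network is post-processed by
fitting the lattice that best explains it.  Candidate lattices are generated
from anchor pairs (a, b): the basis is v = b - a together with its exact
90-degree rotation of equal length (regular square lattice; oblique lattices
from tilted collection are out of scope).  Anchor pairs come from pairing
each high-probability-region centroid with its K nearest neighbours, and the
winning pair minimizes the pixelwise cost

    cost(a, b) = (1/N) * sum_px [ lambda1 * L * (1 - O) + lambda2 * (1 - L) * O ]

where L is the binary rasterization of the candidate lattice (disks at every
lattice point) and N the pixel count.  lambda1 penalizes lattice tiles with
no probability mass (false positives), lambda2 probability mass off the
lattice (false negatives).  Fitting extends detections to holes the network
missed while discarding spurious responses.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ProbabilityMap",
    "Lattice",
    "LatticeFitConfig",
    "HoleCrop",
    "LatticeAnchorError",
    "normalize_medium_mag",
    "extract_centroids",
    "candidate_pairs",
    "generate_lattice",
    "rasterize_lattice",
    "lattice_cost",
    "fit_lattice",
    "score_and_crop",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class LatticeAnchorError(RuntimeError):
    """Raised when a lattice cannot be anchored (fewer than two centroids)."""


@dataclass
class ProbabilityMap:
    """Per-pixel hole-center probability in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("probability values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n_pixels(self) -> int:
        return self.values.size


@dataclass
class Lattice:
    anchor_a: np.ndarray
    anchor_b: np.ndarray
    basis: np.ndarray              # (2, 2): rows v and v-perp, equal length
    points: np.ndarray             # (n, 2) lattice sites inside the image
    cost: float | None = None

    @property
    def pitch(self) -> float:
        return float(np.linalg.norm(self.basis[0]))


@dataclass
class LatticeFitConfig:
    """Knobs of the lattice search.

    ``render_radius=None`` derives the disk radius as ``0.25 * pitch`` per
    candidate pair, keeping the cost comparable across pitches.
    ``tile_prob_threshold`` enables the precision-oriented variant that drops
    lattice tiles with low summed probability.
    """

    lambda_fp: float = 1.0
    lambda_fn: float = 4.0
    k_neighbors: int = 6
    region_threshold: float = 0.5
    render_radius: float | None = None
    tile_prob_threshold: float | None = None
    # minimum admissible anchor spacing; None derives it from the detected
    # region sizes (twice the median region-equivalent radius — holes cannot
    # overlap, so no real lattice can be tighter)
    min_pitch: float | None = None
    # rescale lambda_fn so the missed-mass penalty is commensurate with the
    # lattice-area penalty on low-mass maps (early-training network output
    # concentrates probability in narrow spikes); a full lattice of derived-
    # radius disks covers a pi/16 pixel fraction, which sets the reference
    auto_balance: bool = False

    def __post_init__(self) -> None:
        if self.lambda_fp <= 0 or self.lambda_fn <= 0:
            raise ValueError("lambda weights must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (0.0 < self.region_threshold < 1.0):
            raise ValueError("region_threshold must be in (0, 1)")


@dataclass
class HoleCrop:
    pixels: np.ndarray
    normalized_pixels: np.ndarray
    center: np.ndarray
    unet_score: float


def normalize_medium_mag(image: np.ndarray) -> np.ndarray:
    """Standardize an image to zero mean, unit variance (dose control).

    Constant images map to all zeros through an sd floor.
    """
    image = np.asarray(image, float)
    if image.size == 0:
        raise ValueError("empty image")
    sd = image.std()
    if sd < 1e-12:
        return np.zeros_like(image)
    return (image - image.mean()) / sd


def extract_centroids(pmap: ProbabilityMap, region_threshold: float = 0.5) -> np.ndarray:
    """Probability-weighted centroids of high-probability regions.

    Regions are 4-connected components of ``values >= region_threshold``;
    each centroid is the probability-weighted mean pixel position of its
    component.  Returns an (n, 2) array (possibly empty), ordered by
    component label (scan order).
    """
    if not (0.0 < region_threshold < 1.0):
        raise ValueError("region_threshold must be in (0, 1)")
    v = pmap.values
    labels, n = ndimage.label(v >= region_threshold, structure=_FOUR_CONN)
    if n == 0:
        return np.empty((0, 2), float)
    cents = ndimage.center_of_mass(v, labels, np.arange(1, n + 1))
    return np.asarray(cents, float).reshape(-1, 2)


def derive_min_pitch(pmap: ProbabilityMap, region_threshold: float) -> float:
    """Smallest admissible anchor spacing, from the detected region sizes.

    Holes cannot overlap, so no genuine lattice pitch can be below twice the
    typical region-equivalent radius at the extraction threshold; pairs of
    sub-peak centroids inside one hole would otherwise seed degenerate
    tight lattices.
    """
    regions = (pmap.values >= region_threshold)
    labels, n = ndimage.label(regions, structure=_FOUR_CONN)
    if n == 0:
        return 2.0
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    r_eq = math.sqrt(float(np.median(areas)) / math.pi)
    return max(2.0, 2.0 * r_eq)


def candidate_pairs(centroids: np.ndarray, k_neighbors: int = 6) -> list[tuple[np.ndarray, np.ndarray]]:
    """Anchor-pair candidates: each centroid with its K nearest others.

    Unordered duplicates are kept once (first occurrence wins); neighbour
    ties in distance are broken by (row, col) order.  K trades fit quality
    for run time.
    """
    centroids = np.asarray(centroids, float)
    n = len(centroids)
    if n < 2:
        raise LatticeAnchorError(
            f"need at least 2 centroids to anchor a lattice, got {n}"
        )
    k = min(k_neighbors, n - 1)
    tree = cKDTree(centroids)
    dists, idxs = tree.query(centroids, k=n)  # includes self at distance 0
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        neigh = [j for j in idxs[i] if j != i]
        # stable tie-break: sort by (distance, row, col)
        neigh.sort(key=lambda j: (np.linalg.norm(centroids[j] - centroids[i]),
                                  centroids[j][0], centroids[j][1]))
        for j in neigh[:k]:
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((centroids[i].copy(), centroids[int(j)].copy()))
    return pairs


def generate_lattice(a, b, shape: tuple[int, int],
                     render_radius: float | None = None) -> Lattice:
    """Regular square lattice through anchors a and b.

    Basis is v = b - a and its 90-degree rotation v-perp (equal length);
    points are all a + i*v + j*v_perp inside the half-open image bounds
    [0, H) x [0, W).  Anchors closer than ``2 * render_radius`` (holes would
    overlap) or coincident are rejected.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    v = b - a
    pitch = float(np.linalg.norm(v))
    if pitch == 0.0:
        raise ValueError("anchor points must differ")
    if render_radius is not None and pitch < 2 * render_radius:
        raise ValueError(
            f"anchor spacing {pitch:.2f} < hole diameter {2 * render_radius:.2f}"
        )
    vperp = np.array([-v[1], v[0]])
    H, W = shape
    basis = np.stack([v, vperp])

    # index bounds from the image corners expressed in lattice coordinates
    corners = np.array([[0, 0], [0, W], [H, 0], [H, W]], float) - a
    ij = corners @ np.linalg.inv(basis)
    i_lo, j_lo = np.floor(ij.min(axis=0)).astype(int) - 1
    i_hi, j_hi = np.ceil(ij.max(axis=0)).astype(int) + 1
    ii, jj = np.meshgrid(np.arange(i_lo, i_hi + 1), np.arange(j_lo, j_hi + 1),
                         indexing="ij")
    pts = a + ii[..., None] * v + jj[..., None] * vperp
    pts = pts.reshape(-1, 2)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < H) & (pts[:, 1] >= 0) & (pts[:, 1] < W)
    pts = pts[keep]
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return Lattice(anchor_a=a, anchor_b=b, basis=basis, points=pts[order])


def rasterize_lattice(lattice: Lattice, shape: tuple[int, int],
                      render_radius: float) -> np.ndarray:
    """Binary map with a disk of ``render_radius`` at every lattice point."""
    H, W = shape
    L = np.zeros((H, W), bool)
    r = render_radius
    ri = int(math.ceil(r))
    for cy, cx in lattice.points:
        r0, r1 = max(int(math.floor(cy)) - ri, 0), min(int(math.ceil(cy)) + ri + 1, H)
        c0, c1 = max(int(math.floor(cx)) - ri, 0), min(int(math.ceil(cx)) + ri + 1, W)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        L[r0:r1, c0:c1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    return L


def lattice_cost(pmap: ProbabilityMap, lattice: Lattice,
                 config: LatticeFitConfig) -> float:
    """Pixelwise lambda-weighted disagreement between lattice and map."""
    O = pmap.values
    radius = config.render_radius if config.render_radius is not None \
        else 0.25 * lattice.pitch
    L = rasterize_lattice(lattice, O.shape, radius).astype(float)
    N = pmap.n_pixels
    cost = (config.lambda_fp * L * (1.0 - O) + config.lambda_fn * (1.0 - L) * O).sum() / N
    return float(cost)


def fit_lattice(pmap: ProbabilityMap, config: LatticeFitConfig | None = None,
                centroids: np.ndarray | None = None) -> Lattice:
    """Best-fitting regular square lattice for a probability map.

    Searches the anchor pairs from :func:`candidate_pairs` and returns the
    lattice of smallest :func:`lattice_cost`; ties keep the earlier pair in
    candidate order.  ``centroids`` may be supplied to bypass extraction
    (e.g. for exhaustive-search comparisons).
    """
    config = config or LatticeFitConfig()
    if centroids is None:
        centroids = extract_centroids(pmap, config.region_threshold)
    pairs = candidate_pairs(centroids, config.k_neighbors)

    min_pitch = config.min_pitch
    if min_pitch is None:
        min_pitch = derive_min_pitch(pmap, config.region_threshold)

    if config.auto_balance:
        mean_mass = float(pmap.values.mean())
        if mean_mass > 0:
            factor = max(1.0, (math.pi / 16.0) / mean_mass)
            config = dataclasses.replace(config,
                                         lambda_fn=config.lambda_fn * factor)

    best: Lattice | None = None
    for a, b in pairs:
        if np.linalg.norm(b - a) < min_pitch:
            continue
        try:
            lat = generate_lattice(a, b, pmap.values.shape, config.render_radius)
        except ValueError:
            continue
        lat.cost = lattice_cost(pmap, lat, config)
        if best is None or lat.cost < best.cost:
            best = lat
    if best is None:
        raise LatticeAnchorError("no admissible anchor pair found")
    return best


def score_and_crop(pmap: ProbabilityMap, image: np.ndarray, lattice: Lattice,
                   config: LatticeFitConfig | None = None) -> list[HoleCrop]:
    """One crop per lattice point, scored by summed map probability.

    The crop window is a square of side ``round(pitch)`` centered on the
    lattice point, clamped at image borders; ``unet_score`` is the sum of map
    values inside the window.  With ``tile_prob_threshold`` set, tiles below
    the threshold are dropped — trading recall for precision.
    """
    config = config or LatticeFitConfig()
    O = pmap.values
    H, W = O.shape
    side = max(int(round(lattice.pitch)), 1)
    half = side / 2.0
    crops: list[HoleCrop] = []
    for cy, cx in lattice.points:
        r0 = max(int(round(cy - half)), 0)
        r1 = min(int(round(cy + half)), H)
        c0 = max(int(round(cx - half)), 0)
        c1 = min(int(round(cx + half)), W)
        if r0 >= r1 or c0 >= c1:
            continue
        score = float(O[r0:r1, c0:c1].sum())
        if config.tile_prob_threshold is not None and score < config.tile_prob_threshold:
            continue
        pix = np.asarray(image, float)[r0:r1, c0:c1]
        sd = max(float(pix.std()), 1e-8)
        crops.append(HoleCrop(pixels=pix,
                              normalized_pixels=(pix - pix.mean()) / sd,
                              center=np.array([cy, cx]),
                              unet_score=score))
    return crops
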