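"""Seeded simulators for low- and medium-magnification cryo-EM scenes.

Two scene families are generated with full ground truth:

* **Grid scenes** — low-magnification images of the grid mesh: bright squares
  (thin foil windows) on dark grid bars, all squares sharing one unknown
  rotation angle.  Pixel values are Poisson counts, matching the physics of a
  low-dose counting detector and the mixture model used for segmentation.
* **Hole scenes** — medium-magnification images of a square interior: circular
  holes on a regular, axis-aligned square lattice, with variable contrast sign
  (holes may be darker than the substrate on carbon grids), irregular dark
  contamination blobs, hole dropout, and additive Gaussian noise on the
  normalized intensity scale.

Coordinates are (row, col), 0-based, pixel centers at integers; image bounds
are half-open [0, H) x [0, W).  Every generator is deterministic for a fixed
spec (the seed is part of the spec).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSceneSpec",
    "GridScene",
    "HoleSceneSpec",
    "HoleScene",
    "generate_grid_scene",
    "generate_hole_scene",
    "generate_probability_map",
]


# ---------------------------------------------------------------------------
# Low magnification: grid scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSceneSpec:
    """Parameters of a synthetic low-magnification grid image.

    ``bar_rate`` and ``square_rate`` are expected photon counts per pixel on
    the grid bars and inside squares respectively; ``bar_rate < square_rate``
    because bars are thick metal and squares are thin foil.
    """

    image_height_px: int
    image_width_px: int
    mesh_pitch_px: float
    square_side_px: float
    rotation_deg: float
    bar_rate: float
    square_rate: float
    broken_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rotation_deg < 90):
            raise ValueError("rotation_deg must lie in [0, 90)")
        if not (self.square_side_px < self.mesh_pitch_px):
            raise ValueError("square_side_px must be smaller than mesh_pitch_px")
        if not (0 <= self.bar_rate < self.square_rate):
            raise ValueError("need 0 <= bar_rate < square_rate")
        if not (0.0 <= self.broken_fraction <= 1.0):
            raise ValueError("broken_fraction must be in [0, 1]")
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")


@dataclass
class RotatedBox:
    """Rectangle given by center (row, col), side lengths and angle (deg)."""

    center: tuple[float, float]
    width: float
    height: float
    angle_deg: float

    def corners(self) -> np.ndarray:
        """4x2 array of (row, col) corners, counter-clockwise."""
        t = math.radians(self.angle_deg)
        # unit axes of the box frame in (row, col) coordinates
        u = np.array([math.sin(t), math.cos(t)])    # along width
        v = np.array([math.cos(t), -math.sin(t)])   # along height
        c = np.asarray(self.center, float)
        hw, hh = self.width / 2.0, self.height / 2.0
        return np.array([c - hw * u - hh * v,
                         c + hw * u - hh * v,
                         c + hw * u + hh * v,
                         c - hw * u + hh * v])


@dataclass
class GridScene:
    image: np.ndarray
    true_boxes: list[RotatedBox]
    selected_labels: np.ndarray          # bool per box: worth collecting
    spec: GridSceneSpec
    interior_mask: np.ndarray = field(repr=False, default=None)  # rendered square pixels

    def to_json(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "true_boxes": [
                {"cy": b.center[0], "cx": b.center[1], "w": b.width,
                 "h": b.height, "angle_deg": b.angle_deg}
                for b in self.true_boxes
            ],
            "selected_labels": [bool(x) for x in self.selected_labels],
        }


def _mesh_frame(spec: GridSceneSpec):
    """Rotation taking image (row, col) into the mesh frame (u, v)."""
    t = math.radians(spec.rotation_deg)
    rot = np.array([[math.cos(t), -math.sin(t)],
                    [math.sin(t), math.cos(t)]])
    center = np.array([spec.image_height_px / 2.0, spec.image_width_px / 2.0])
    return rot, center


def generate_grid_scene(spec: GridSceneSpec) -> GridScene:
    """Render a grid scene: Poisson image plus ground-truth square boxes.

    Squares sit at mesh positions ``pitch/2 + i*pitch`` in a frame rotated by
    ``rotation_deg`` about the image center; only squares fully inside the
    image are rendered and recorded.  ``broken_fraction`` of the squares have
    a random half-plane erased (cracked square); they stay in ``true_boxes``
    with ``selected_labels`` False.
    """
    H, W = spec.image_height_px, spec.image_width_px
    rot, center = _mesh_frame(spec)
    pitch, side = spec.mesh_pitch_px, spec.square_side_px

    # candidate mesh indices generously covering the image diagonal
    half_diag = math.hypot(H, W) / 2.0
    n = int(math.ceil(half_diag / pitch)) + 2
    idx = np.arange(-n, n + 1)
    half = side / 2.0

    boxes: list[RotatedBox] = []
    for i in idx:
        for j in idx:
            uv = np.array([pitch / 2.0 + i * pitch, pitch / 2.0 + j * pitch])
            # mesh frame -> image frame (rotate about center)
            c = rot.T @ uv + center
            box = RotatedBox(center=(float(c[0]), float(c[1])), width=side,
                             height=side, angle_deg=spec.rotation_deg)
            corners = box.corners()
            if (corners[:, 0] >= 0).all() and (corners[:, 0] <= H - 1).all() \
                    and (corners[:, 1] >= 0).all() and (corners[:, 1] <= W - 1).all():
                boxes.append(box)
    if not boxes:
        raise ValueError(
            f"no complete square fits a {H}x{W} image with pitch {pitch} "
            f"and side {side}"
        )
    # stable order: by mesh coordinates (row-major in the mesh frame)
    keys = []
    for b in boxes:
        uv = rot @ (np.asarray(b.center) - center)
        keys.append((round(uv[0] / pitch), round(uv[1] / pitch)))
    order = np.lexsort((np.array([k[1] for k in keys]), np.array([k[0] for k in keys])))
    boxes = [boxes[k] for k in order]

    rng = np.random.default_rng(spec.seed)
    n_boxes = len(boxes)
    n_broken = int(round(spec.broken_fraction * n_boxes))
    broken = np.zeros(n_boxes, bool)
    if n_broken:
        broken[rng.choice(n_boxes, size=n_broken, replace=False)] = True

    # rasterize interiors
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    pts = np.stack([rr.ravel() - center[0], cc.ravel() - center[1]])
    uv = rot @ pts
    u = uv[0].reshape(H, W)
    v = uv[1].reshape(H, W)
    inside = np.zeros((H, W), bool)
    for k, b in enumerate(boxes):
        buv = rot @ (np.asarray(b.center) - center)
        member = (np.abs(u - buv[0]) <= half) & (np.abs(v - buv[1]) <= half)
        if broken[k]:
            # erase a random half-plane through a point offset from the center
            theta = rng.uniform(0, 2 * math.pi)
            nvec = np.array([math.cos(theta), math.sin(theta)])
            offset = rng.uniform(-0.3, 0.3) * side
            signed = (u - buv[0]) * nvec[0] + (v - buv[1]) * nvec[1]
            member &= signed < offset
        inside |= member

    lam = np.where(inside, spec.square_rate, spec.bar_rate)
    image = rng.poisson(lam).astype(np.float64)

    return GridScene(image=image, true_boxes=boxes,
                     selected_labels=~broken, spec=spec, interior_mask=inside)


# ---------------------------------------------------------------------------
# Medium magnification: hole scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoleSceneSpec:
    """Parameters of a synthetic medium-magnification image.

    Intensities are on a normalized scale (background 0, hole offset
    ``contrast_sign``); ``noise_sd`` is the standard deviation of additive
    Gaussian noise on that scale.  ``operator_fraction`` controls how many of
    the good visible holes carry an operator selection point — operators
    target incompletely, so the default leaves some holes unlabeled.
    """

    image_height_px: int
    image_width_px: int
    lattice_pitch_px: float
    hole_radius_px: float
    lattice_origin_px: tuple[float, float] = (0.0, 0.0)
    contrast_sign: int = 1
    noise_sd: float = 0.15
    n_contaminants: int = 0
    dropout_fraction: float = 0.0
    operator_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 * self.hole_radius_px < self.lattice_pitch_px):
            raise ValueError("holes must not overlap: need 2*radius < pitch")
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise ValueError("dropout_fraction must be in [0, 1]")
        if self.contrast_sign not in (+1, -1):
            raise ValueError("contrast_sign must be +1 or -1")
        oy, ox = self.lattice_origin_px
        if not (0 <= oy < self.image_height_px and 0 <= ox < self.image_width_px):
            raise ValueError("lattice_origin_px must lie inside the image")
        if not (0.0 <= self.operator_fraction <= 1.0):
            raise ValueError("operator_fraction must be in [0, 1]")


@dataclass
class HoleScene:
    image: np.ndarray
    true_centers: np.ndarray             # (n, 2) float, exact lattice points
    visible_mask: np.ndarray             # bool per center
    good_labels: np.ndarray              # bool per center: clean & visible
    operator_points: np.ndarray          # (m, 2) jittered subset of centers
    spec: HoleSceneSpec

    def to_json(self) -> dict:
        return {
            "spec": dataclasses.asdict(self.spec),
            "true_centers": self.true_centers.tolist(),
            "visible_mask": [bool(x) for x in self.visible_mask],
            "good_labels": [bool(x) for x in self.good_labels],
            "operator_points": self.operator_points.tolist(),
        }


def _lattice_points(origin, pitch, H, W) -> np.ndarray:
    oy, ox = origin
    # extend the index range to cover offsets below the origin as well
    i0 = -int(math.floor(oy / pitch))
    i1 = int(math.floor((H - 1e-9 - oy) / pitch))
    j0 = -int(math.floor(ox / pitch))
    j1 = int(math.floor((W - 1e-9 - ox) / pitch))
    pts = [(oy + i * pitch, ox + j * pitch)
           for i in range(i0, i1 + 1) for j in range(j0, j1 + 1)]
    pts = [(r, c) for r, c in pts if 0 <= r < H and 0 <= c < W]
    return np.array(pts, float).reshape(-1, 2)


def generate_hole_scene(spec: HoleSceneSpec) -> HoleScene:
    """Render a hole scene and its ground truth.

    Holes are disks of ``hole_radius_px`` at the lattice points; a
    ``dropout_fraction`` of them is omitted from rendering (thick ice,
    occlusion) but kept in ``true_centers`` with ``visible_mask`` False.
    Contaminants are irregular dark blobs (unions of 2-4 random disks); a
    hole overlapped by a contaminant gets ``good_labels`` False.  Operator
    points are sampled from the good holes with isotropic Gaussian jitter of
    sd ``hole_radius_px / 4``, truncated inside the hole disk.
    """
    H, W = spec.image_height_px, spec.image_width_px
    rng = np.random.default_rng(spec.seed)
    centers = _lattice_points(spec.lattice_origin_px, spec.lattice_pitch_px, H, W)
    n = len(centers)
    if n == 0:
        raise ValueError("lattice origin/pitch leave no point inside the image")

    visible = np.ones(n, bool)
    n_drop = int(round(spec.dropout_fraction * n))
    if n_drop:
        visible[rng.choice(n, size=n_drop, replace=False)] = False

    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    image = np.zeros((H, W), float)
    r2 = spec.hole_radius_px ** 2
    for k in np.flatnonzero(visible):
        cy, cx = centers[k]
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        image[d2 <= r2] = float(spec.contrast_sign)

    # contamination: unions of a few dark disks, anywhere in the image
    contaminated = np.zeros(n, bool)
    for _ in range(spec.n_contaminants):
        base = rng.uniform([0, 0], [H, W])
        n_lobes = rng.integers(2, 5)
        for _ in range(n_lobes):
            off = rng.normal(0, spec.hole_radius_px * 0.6, size=2)
            rad = rng.uniform(0.4, 1.0) * spec.hole_radius_px
            cy, cx = base + off
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            image[d2 <= rad ** 2] = -1.5
            dist = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
            contaminated |= dist <= rad + spec.hole_radius_px
    good = visible & ~contaminated

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(H, W))

    # operator selections: a fraction of the good holes, jittered
    good_idx = np.flatnonzero(good)
    n_sel = int(round(spec.operator_fraction * len(good_idx)))
    sel = rng.choice(good_idx, size=n_sel, replace=False) if n_sel else np.array([], int)
    sel.sort()
    pts = []
    for k in sel:
        while True:
            jit = rng.normal(0.0, spec.hole_radius_px / 4.0, size=2)
            if np.hypot(*jit) < 0.9 * spec.hole_radius_px:
                break
        p = centers[k] + jit
        pts.append(np.clip(p, [0, 0], [H - 1, W - 1]))
    operator_points = np.array(pts, float).reshape(-1, 2)

    return HoleScene(image=image, true_centers=centers, visible_mask=visible,
                     good_labels=good, operator_points=operator_points, spec=spec)


# ---------------------------------------------------------------------------
# Synthetic probability maps (heatmaps without a trained network)
# ---------------------------------------------------------------------------

def generate_probability_map(scene: HoleScene, blob_sigma: float,
                             n_spurious: int = 0, seed: int = 0):
    """Build a hole-center probability map directly from ground truth.

    Places a unit-peak Gaussian bump at every *visible* true center plus
    ``n_spurious`` bumps at random off-lattice positions (kept at least
    ``0.35 * pitch`` from every true center so spurious regions never contain
    a real center).  Bumps are summed and clipped to [0, 1].  This exercises
    the lattice-fitting post-process in isolation from network training.
    """
    from cryotarget.lattice import ProbabilityMap

    if blob_sigma <= 0:
        raise ValueError("blob_sigma must be positive")
    H, W = scene.image.shape
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    values = np.zeros((H, W), float)

    def add_bump(cy, cx):
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        values[:] += np.exp(-d2 / (2.0 * blob_sigma ** 2))

    for k in np.flatnonzero(scene.visible_mask):
        add_bump(*scene.true_centers[k])

    min_gap = 0.35 * scene.spec.lattice_pitch_px
    placed = 0
    guard = 0
    while placed < n_spurious:
        guard += 1
        if guard > 10000:
            raise RuntimeError("could not place spurious bumps off-lattice")
        cy, cx = rng.uniform([0, 0], [H - 1, W - 1])
        d = np.hypot(scene.true_centers[:, 0] - cy, scene.true_centers[:, 1] - cx)
        if d.min() > min_gap:
            add_bump(cy, cx)
            placed += 1

    np.clip(values, 0.0, 1.0, out=values)
    return ProbabilityMap(values=values)


def standard_grid_scenes(n_scenes: int, seed: int) -> list[GridScene]:
    """Seeded batch of reference low-magnification scenes.

    256 px images with a 64 px mesh pitch and 40 px squares; each scene draws
    its own mesh rotation uniformly over [0, 90) and renders 10% of squares
    broken, the clean-contrast regime of a typical gold grid atlas
    (bar rate 4, square rate 40 counts).
    """
    scenes = []
    for i in range(n_scenes):
        rng = np.random.default_rng(seed + i)
        spec = GridSceneSpec(
            image_height_px=256, image_width_px=256, mesh_pitch_px=64,
            square_side_px=40, rotation_deg=float(rng.uniform(0, 90)),
            bar_rate=4, square_rate=40, broken_fraction=0.1, seed=seed + i)
        scenes.append(generate_grid_scene(spec))
    return scenes


def standard_hole_scene_spec(seed: int, image_size: int = 128,
                             contrast_sign: int = 1) -> HoleSceneSpec:
    """The reference medium-magnification scene conditions.

    128 px scenes with a 32 px lattice pitch, 8 px hole radius, random lattice
    origin, 15% intensity noise, one contamination blob and 10% hole dropout —
    a scene a real session would call moderately difficult.  The lattice
    origin is drawn from the seed so every scene has a different phase.
    """
    rng = np.random.default_rng(seed)
    pitch = image_size / 4.0
    origin = tuple(rng.uniform(pitch / 8.0, pitch * 7.0 / 8.0, 2))
    return HoleSceneSpec(
        image_height_px=image_size, image_width_px=image_size,
        lattice_pitch_px=pitch, hole_radius_px=pitch / 4.0,
        lattice_origin_px=origin, contrast_sign=contrast_sign,
        noise_sd=0.15, n_contaminants=1, dropout_fraction=0.1, seed=seed)


def standard_hole_scenes(n_scenes: int, seed: int, image_size: int = 128,
                         contrast_mix: bool = True) -> list[HoleScene]:
    """Seeded batch of reference hole scenes.

    With ``contrast_mix`` half the scenes (odd indices) are contrast-inverted,
    emulating carbon-grid sessions where holes are darker than the substrate.
    """
    scenes = []
    for i in range(n_scenes):
        sign = -1 if (contrast_mix and i % 2 == 1) else 1
        scenes.append(generate_hole_scene(
            standard_hole_scene_spec(seed + i, image_size, sign)))
    return scenes


# ---------------------------------------------------------------------------
# Sidecar helpers
# ---------------------------------------------------------------------------

def save_scene(scene, image_path, sidecar_path) -> None:
    """Write the scene image plus a JSON ground-truth sidecar."""
    from cryotarget import io as ctio

    ctio.write_image(image_path, scene.image)
    with open(sidecar_path, "w") as fh:
        json.dump(scene.to_json(), fh, indent=1)
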