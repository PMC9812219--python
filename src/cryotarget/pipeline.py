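"""Two-stage targeting pipeline orchestration.

Stage one takes a low-magnification image to a ranked list of square
targets; stage two takes a medium-magnification image to a fitted hole
lattice with ranked hole targets.  The stages are separate entry points
because on a microscope they interleave with acquisition.  Every output
carries a provenance block (config hash, seed, package version) so targeting
decisions are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from cryotarget import io as ctio
from cryotarget.features import ScoredTarget, rank_targets, square_features, unet_score_classifier
from cryotarget.lattice import (
    Lattice,
    LatticeAnchorError,
    LatticeFitConfig,
    ProbabilityMap,
    fit_lattice,
    score_and_crop,
)
from cryotarget.mixture import DegenerateMixtureError, fit_poisson_mixture, segment_squares
from cryotarget.squares import crop_squares, extract_polygons, find_optimal_angle

logger = logging.getLogger("cryotarget")

__all__ = ["PipelineConfig", "TargetList", "run_square_stage", "run_hole_stage"]

EXIT_IO_ERROR = 2
EXIT_ANCHOR_ERROR = 3


@dataclass
class PipelineConfig:
    """Run-level settings for both stages."""

    # square stage
    mixture_tol: float = 1e-6
    mixture_max_iter: int = 200
    min_pixels: int | None = None
    pad_fraction: float = 0.05
    square_classifier: str | None = None    # checkpoint path; None = heuristic
    # hole stage
    hole_model: str | None = None           # U-Net checkpoint path
    lattice: LatticeFitConfig = field(default_factory=LatticeFitConfig)
    hole_classifier: str = "unet_score"     # or a HoleCNN checkpoint path
    # run
    seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class TargetList:
    source: str
    stage: str                      # "square" | "hole"
    entries: list[ScoredTarget]
    provenance: dict
    lattice: Lattice | None = None
    error: str | None = None

    def to_json(self) -> dict:
        out = {
            "source": self.source,
            "stage": self.stage,
            "provenance": self.provenance,
            "targets": [
                {"score": t.score, "rank": t.rank, "level": t.level,
                 **_loc_json(t.location)}
                for t in self.entries
            ],
        }
        if self.lattice is not None:
            out["lattice"] = {
                "a": list(map(float, self.lattice.anchor_a)),
                "b": list(map(float, self.lattice.anchor_b)),
                "pitch": self.lattice.pitch,
                "cost": self.lattice.cost,
            }
        if self.error is not None:
            out["error"] = self.error
        return out


def _loc_json(loc) -> dict:
    if hasattr(loc, "center"):
        return {"cy": float(loc.center[0]), "cx": float(loc.center[1]),
                "h": float(loc.height), "w": float(loc.width),
                "angle_deg": float(loc.angle_deg)}
    arr = np.asarray(loc, float).ravel()
    return {"cy": float(arr[0]), "cx": float(arr[1])}


def _provenance(config: PipelineConfig) -> dict:
    from cryotarget import __version__

    return {"config_hash": config.config_hash(), "seed": config.seed,
            "version": __version__}


def _heuristic_square_scores(crops) -> np.ndarray:
    """Fallback ranking without a trained classifier.

    Operators favour large, bright squares, so the score is a logistic
    squash of standardized area + mean intensity.
    """
    feats = [square_features(c) for c in crops]
    area = np.array([f.area for f in feats], float)
    mean = np.array([f.mean_intensity for f in feats], float)

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    return 1.0 / (1.0 + np.exp(-(z(area) + z(mean))))


def run_square_stage(image, config: PipelineConfig | None = None,
                     source: str = "<array>") -> TargetList:
    """Low-magnification image -> ranked square targets.

    ``image`` is a path or a 2-D array.  A contrast-free image (degenerate
    mixture) yields a valid empty target list with a warning.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        source = str(image)
        image = ctio.read_image(image)

    provenance = _provenance(config)
    fit = fit_poisson_mixture(image, max_iter=config.mixture_max_iter,
                              tol=config.mixture_tol)
    if fit.degenerate:
        logger.warning("degenerate mixture fit (no square/background contrast); "
                       "emitting empty target list")
        return TargetList(source=source, stage="square", entries=[],
                          provenance=provenance, error="degenerate_mixture")
    mask = segment_squares(image, fit)
    polygons = extract_polygons(mask, min_pixels=config.min_pixels)
    if not polygons:
        return TargetList(source=source, stage="square", entries=[],
                          provenance=provenance)
    boxset = find_optimal_angle(polygons)
    crops = crop_squares(image, boxset, pad_fraction=config.pad_fraction)

    if config.square_classifier:
        from cryotarget.nn.classifiers import load_classifier

        model = load_classifier(config.square_classifier)
        scores = np.array([model.score(c) for c in crops])
    else:
        scores = _heuristic_square_scores(crops)
    entries = rank_targets([c.source_box for c in crops], scores, level="square")
    logger.info("square stage: %d targets in %.2fs", len(entries),
                time.perf_counter() - t0)
    return TargetList(source=source, stage="square", entries=entries,
                      provenance=provenance)


def run_hole_stage(image, config: PipelineConfig,
                   source: str = "<array>") -> TargetList:
    """Medium-magnification image -> fitted lattice and ranked hole targets.

    Raises :class:`LatticeAnchorError` when the probability map yields fewer
    than two centroids (the CLI maps this to a distinct exit code).
    """
    from cryotarget.nn.unet import load_unet, unet_predict

    t0 = time.perf_counter()
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        source = str(image)
        image = ctio.read_image(image)
    if config.hole_model is None:
        raise ValueError("config.hole_model (U-Net checkpoint) is required")
    model, _sigma = load_unet(config.hole_model)

    pmap = unet_predict(model, image)
    # calibrate to unit peak: the lattice cost weighs covered vs uncovered
    # probability mass, so relative evidence is what matters
    peak = float(pmap.values.max())
    if peak > 0:
        pmap = ProbabilityMap(values=pmap.values / peak)

    # adaptive centroid threshold: halve until the map yields enough anchor
    # candidates (weak maps concentrate mass on few holes early in training)
    from cryotarget.lattice import extract_centroids

    lat_cfg = config.lattice
    threshold = lat_cfg.region_threshold
    centroids = extract_centroids(pmap, threshold)
    while len(centroids) < 4 and threshold > 0.02:
        threshold /= 2.0
        centroids = extract_centroids(pmap, threshold)
    lat_cfg = dataclasses.replace(lat_cfg, region_threshold=threshold,
                                  auto_balance=True)

    lattice = fit_lattice(pmap, lat_cfg, centroids=centroids)
    crops = score_and_crop(pmap, image, lattice, lat_cfg)

    if config.hole_classifier == "unet_score":
        entries = unet_score_classifier(crops)
    else:
        from cryotarget.nn.classifiers import load_classifier

        clf = load_classifier(config.hole_classifier)
        scores = np.array([clf.score(c) for c in crops])
        entries = rank_targets([c.center for c in crops], scores, level="hole")
    logger.info("hole stage: %d targets, pitch %.2f px, in %.2fs",
                len(entries), lattice.pitch, time.perf_counter() - t0)
    return TargetList(source=source, stage="hole", entries=entries,
                      provenance=_provenance(config), lattice=lattice)
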