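"""Detection and ranking metrics with one-to-one containment matching.

Hole detections are points, not boxes, so matching is point-in-hole with a
strict one-to-one rule: a hole containing exactly one predicted point is a
true positive; a hole containing zero or two-plus points is a false
negative; a predicted point is a false positive when it falls in no hole or
only in holes that also contain other predicted points.  Precision, recall
and F1 are pooled per session and macro-averaged across sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from shapely.geometry import Polygon
from sklearn.metrics import accuracy_score, average_precision_score, roc_auc_score

__all__ = [
    "GroundTruthHoles",
    "MatchResult",
    "SessionReport",
    "match_predictions",
    "session_metrics",
    "ranking_metrics",
    "match_boxes",
]


@dataclass
class GroundTruthHoles:
    """Reference hole centers with a containment radius.

    ``radius`` may be a scalar (shared) or per-hole array.  Holes must not
    overlap, otherwise containment is ambiguous.
    """

    centers: np.ndarray
    radius: float | np.ndarray

    def __post_init__(self):
        self.centers = np.asarray(self.centers, float).reshape(-1, 2)
        r = np.asarray(self.radius, float)
        self.radius = np.broadcast_to(r, (len(self.centers),)).astype(float)
        if len(self.centers) and self.radius.min() <= 0:
            raise ValueError("containment radius must be positive")
        n = len(self.centers)
        for i in range(n):
            d = np.hypot(*(self.centers[i + 1:] - self.centers[i]).T)
            if np.any(d < self.radius[i] + self.radius[i + 1:]):
                raise ValueError("overlapping holes: containment is ambiguous")


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    assignments: list[dict] = field(default_factory=list, repr=False)

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)


def match_predictions(points, gt: GroundTruthHoles) -> MatchResult:
    """One-to-one containment matching of predicted points to holes."""
    points = np.asarray(points, float).reshape(-1, 2)
    n_holes = len(gt.centers)
    hole_of_point = np.full(len(points), -1)
    counts = np.zeros(n_holes, int)
    for i, p in enumerate(points):
        if n_holes:
            d = np.hypot(*(gt.centers - p).T)
            inside = np.flatnonzero(d <= gt.radius)
            if len(inside):  # non-overlap guarantees at most one hole
                j = int(inside[0])
                hole_of_point[i] = j
                counts[j] += 1

    tp = int((counts == 1).sum())
    fn = int(n_holes - tp)
    fp = 0
    log = []
    for i, j in enumerate(hole_of_point):
        if j < 0:
            fp += 1
            log.append({"point": i, "hole": None, "kind": "fp_outside"})
        elif counts[j] == 1:
            log.append({"point": i, "hole": int(j), "kind": "tp"})
        else:
            fp += 1
            log.append({"point": i, "hole": int(j), "kind": "fp_crowded"})
    return MatchResult(tp=tp, fp=fp, fn=fn, assignments=log)


@dataclass
class SessionReport:
    per_session: dict              # session_id -> {precision, recall, f1, tp, fp, fn}
    macro_precision: float | None
    macro_recall: float | None
    macro_f1: float | None
    micro_precision: float | None
    micro_recall: float | None
    micro_f1: float | None


def _safe_mean(values):
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def session_metrics(results: list[tuple[str, MatchResult]]) -> SessionReport:
    """Pool counts within each session, then macro-average across sessions.

    Sessions with an undefined precision (no predictions) are excluded from
    the macro precision mean with a warning; micro metrics (global pooled
    counts) are also reported for diagnostics.
    """
    if not results:
        raise ValueError("need at least one session")
    per = {}
    agg: dict[str, np.ndarray] = {}
    for sid, mr in results:
        if sid not in agg:
            agg[sid] = np.zeros(3, int)
        agg[sid] += (mr.tp, mr.fp, mr.fn)
    for sid, (tp, fp, fn) in agg.items():
        pooled = MatchResult(tp=int(tp), fp=int(fp), fn=int(fn))
        if pooled.precision is None:
            warnings.warn(f"session {sid!r}: no predictions, precision undefined; "
                          "excluded from the macro mean")
        per[sid] = {"tp": int(tp), "fp": int(fp), "fn": int(fn),
                    "precision": pooled.precision, "recall": pooled.recall,
                    "f1": pooled.f1}
    tp, fp, fn = (int(sum(a[i] for a in agg.values())) for i in range(3))
    micro = MatchResult(tp=tp, fp=fp, fn=fn)
    return SessionReport(
        per_session=per,
        macro_precision=_safe_mean(v["precision"] for v in per.values()),
        macro_recall=_safe_mean(v["recall"] for v in per.values()),
        macro_f1=_safe_mean(v["f1"] for v in per.values()),
        micro_precision=micro.precision,
        micro_recall=micro.recall,
        micro_f1=micro.f1,
    )


def ranking_metrics(scores, labels) -> tuple[float, float, float]:
    """(ROC AUC, average precision, accuracy at the 0.5 threshold)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC undefined with a single class")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)),
            float(accuracy_score(labels, scores >= 0.5)))


# ---------------------------------------------------------------------------
# Box matching (square detections against ground-truth boxes)
# ---------------------------------------------------------------------------

def _box_polygon(box) -> Polygon:
    corners = box.corners() if hasattr(box, "corners") else np.asarray(box, float)
    return Polygon([(c, r) for r, c in corners])


def box_iou(box_a, box_b) -> float:
    pa, pb = _box_polygon(box_a), _box_polygon(box_b)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union > 0 else 0.0


def match_boxes(pred_boxes, true_boxes, iou_threshold: float = 0.5) -> MatchResult:
    """One-to-one box matching maximizing total IoU (Hungarian assignment);
    pairs below the IoU threshold do not match."""
    n_p, n_t = len(pred_boxes), len(true_boxes)
    if n_p == 0 or n_t == 0:
        return MatchResult(tp=0, fp=n_p, fn=n_t)
    iou = np.zeros((n_p, n_t))
    for i, pb in enumerate(pred_boxes):
        for j, tb in enumerate(true_boxes):
            iou[i, j] = box_iou(pb, tb)
    ri, cj = linear_sum_assignment(-iou)
    matched = iou[ri, cj] >= iou_threshold
    tp = int(matched.sum())
    log = [{"pred": int(i), "true": int(j), "iou": float(iou[i, j])}
           for i, j, ok in zip(ri, cj, matched) if ok]
    return MatchResult(tp=tp, fp=n_p - tp, fn=n_t - tp, assignments=log)
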