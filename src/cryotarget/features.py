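"""Summary-statistic features and baseline rankers for target classification.

Operators mostly judge squares by size and brightness, so simple pixel
statistics of each square crop make strong baselines: mean, maximum and
minimum intensity, variance, kurtosis, skew and crop area.  Logistic
regression and a random forest trained on these features are compared with
the CNN; permutation feature importance explains what drives the ranking.
Hole ranking can additionally reuse the localization network's own output:
the summed per-crop probability is itself a good collect-probability score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_perm_importance
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SquareFeatures",
    "FEATURE_NAMES",
    "FEATURE_NAMES_5",
    "ScoredTarget",
    "ImportanceReport",
    "square_features",
    "feature_matrix",
    "features_to_csv",
    "features_from_csv",
    "train_square_baselines",
    "permutation_importance",
    "unet_score_classifier",
    "rank_targets",
]

FEATURE_NAMES = ("mean_intensity", "max_intensity", "min_intensity",
                 "variance", "kurtosis", "skew", "area")
# reduced variant without the higher moments (both configurations are used
# in practice for the random-forest baseline)
FEATURE_NAMES_5 = ("mean_intensity", "max_intensity", "min_intensity",
                   "variance", "area")


@dataclass
class SquareFeatures:
    """Pixel statistics of one normalized square crop.

    Skew and kurtosis are the standardized third/fourth central moments with
    the Fisher convention (a normal distribution has kurtosis 0); a constant
    crop has skew = kurtosis = 0 by convention.  Variance uses the population
    (n) denominator.  ``area`` is the crop pixel count.
    """

    mean_intensity: float
    max_intensity: float
    min_intensity: float
    variance: float
    kurtosis: float
    skew: float
    area: int

    def as_array(self, names=FEATURE_NAMES) -> np.ndarray:
        return np.array([getattr(self, n) for n in names], float)


@dataclass
class ScoredTarget:
    location: object                # point (row, col) or box
    level: str                      # "square" | "hole"
    score: float
    rank: int                       # 1 = best

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


@dataclass
class ImportanceReport:
    feature_names: tuple[str, ...]
    importances_mean: np.ndarray    # mean metric drop per feature
    importances_std: np.ndarray
    n_repeats: int
    seed: int
    metric: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names,
                             "importance": self.importances_mean,
                             "std": self.importances_std})

    def top_features(self, k: int = 2) -> list[str]:
        order = np.argsort(self.importances_mean)[::-1]
        return [self.feature_names[i] for i in order[:k]]


def square_features(crop) -> SquareFeatures:
    """Compute the 7 summary statistics of a square crop."""
    pix = crop.normalized_pixels if hasattr(crop, "normalized_pixels") \
        else np.asarray(crop, float)
    flat = np.asarray(pix, float).ravel()
    if flat.size == 0:
        raise ValueError("empty crop")
    var = float(flat.var())  # population denominator
    if var < 1e-18:
        sk = kur = 0.0
    else:
        sk = float(stats.skew(flat, bias=True))
        kur = float(stats.kurtosis(flat, fisher=True, bias=True))
    return SquareFeatures(mean_intensity=float(flat.mean()),
                          max_intensity=float(flat.max()),
                          min_intensity=float(flat.min()),
                          variance=var, kurtosis=kur, skew=sk,
                          area=int(flat.size))


def feature_matrix(features: list[SquareFeatures],
                   names=FEATURE_NAMES) -> np.ndarray:
    return np.stack([f.as_array(names) for f in features])


def train_square_baselines(features: list[SquareFeatures], labels, seed: int = 0,
                           feature_set: str = "seven"):
    """Fit logistic-regression and random-forest square rankers.

    ``feature_set`` selects the full 7-statistic configuration or the reduced
    5-feature one (without skew/kurtosis).  Returns ``(lr, rf)``; both emit
    calibrated-ish probabilities via ``predict_proba``.
    """
    names = FEATURE_NAMES if feature_set == "seven" else FEATURE_NAMES_5
    X = feature_matrix(features, names)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to train the baselines")
    lr = make_pipeline(StandardScaler(),
                       LogisticRegression(max_iter=1000, random_state=seed))
    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    lr.fit(X, y)
    rf.fit(X, y)
    return lr, rf


def permutation_importance(model, features, labels, metric: str = "average_precision",
                           n_repeats: int = 10, seed: int = 0,
                           feature_set: str = "seven") -> ImportanceReport:
    """Mean metric drop under independent within-column permutations."""
    names = FEATURE_NAMES if feature_set == "seven" else FEATURE_NAMES_5
    X = features if isinstance(features, np.ndarray) else feature_matrix(features, names)
    y = np.asarray(labels, int)
    res = _sk_perm_importance(model, X, y, scoring=metric,
                              n_repeats=n_repeats, random_state=seed)
    return ImportanceReport(feature_names=names,
                            importances_mean=res.importances_mean,
                            importances_std=res.importances_std,
                            n_repeats=n_repeats, seed=seed, metric=metric)


def features_to_csv(path, features: list[SquareFeatures]) -> None:
    """Write a feature table with the fixed 7-column header."""
    pd.DataFrame([f.as_array() for f in features],
                 columns=list(FEATURE_NAMES)).to_csv(path, index=False)


def features_from_csv(path) -> list[SquareFeatures]:
    df = pd.read_csv(path)
    if tuple(df.columns) != FEATURE_NAMES:
        raise ValueError(f"expected columns {FEATURE_NAMES}, got "
                         f"{tuple(df.columns)}")
    return [SquareFeatures(mean_intensity=r.mean_intensity,
                           max_intensity=r.max_intensity,
                           min_intensity=r.min_intensity,
                           variance=r.variance, kurtosis=r.kurtosis,
                           skew=r.skew, area=int(r.area))
            for r in df.itertuples()]


def rank_targets(locations, scores, level: str) -> list[ScoredTarget]:
    """Build a rank-sorted ScoredTarget list (rank 1 = highest score)."""
    scores = np.asarray(scores, float)
    order = np.argsort(-scores, kind="stable")
    out = []
    for rank, i in enumerate(order, start=1):
        out.append(ScoredTarget(location=locations[i], level=level,
                                score=float(scores[i]), rank=rank))
    return out


def unet_score_classifier(crops, threshold: float = 0.5) -> list[ScoredTarget]:
    """Rank hole crops by their summed localization probability.

    Scores are the per-crop summed network probabilities rescaled to [0, 1]
    by the per-image maximum (an all-zero map gives all-zero scores); the
    ranking is identical to ranking by the raw sums.  ``threshold`` marks the
    classification cut on the rescaled score (callers filter on it).
    """
    raw = np.array([c.unet_score for c in crops], float)
    if raw.size == 0:
        return []
    if raw.min() < 0:
        raise ValueError("unet_score must be nonnegative")
    peak = raw.max()
    scores = raw / peak if peak > 0 else np.zeros_like(raw)
    return rank_targets([c.center for c in crops], scores, level="hole")
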