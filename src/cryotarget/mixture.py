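"""Two-component Poisson mixture segmentation of low-magnification images.

The pixel-intensity histogram of a low-magnification grid image decomposes
into low-count pixels from the thick metal grid bars and high-count pixels
from the thin foil squares.  Fitting a two-component Poisson mixture by EM and
thresholding the posterior of the bright component segments squares from
background without a session-specific intensity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "PoissonMixture",
    "PoissonMixtureFit",
    "fit_poisson_mixture",
    "segment_squares",
    "SegmentationMask",
    "to_counts",
    "DegenerateMixtureError",
]


class DegenerateMixtureError(ValueError):
    """Raised when an image has no square/background contrast to segment."""


@dataclass
class PoissonMixtureFit:
    """EM results: rates ordered so ``rate_low <= rate_high``."""

    rate_low: float
    rate_high: float
    weight_high: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    degenerate: bool = False
    log_likelihood_trace: np.ndarray = field(default=None, repr=False)

    def posterior_high(self, counts: np.ndarray) -> np.ndarray:
        """P(bright component | count) for each pixel."""
        if self.degenerate:
            raise DegenerateMixtureError(
                "mixture fit is degenerate (no intensity contrast)"
            )
        lo = _poisson_logpmf(counts, self.rate_low) + np.log1p(-self.weight_high)
        hi = _poisson_logpmf(counts, self.rate_high) + np.log(self.weight_high)
        m = np.maximum(lo, hi)
        return np.exp(hi - (m + np.log(np.exp(lo - m) + np.exp(hi - m))))


@dataclass
class SegmentationMask:
    mask: np.ndarray  # bool raster, True = square-class pixel


def _poisson_logpmf(k: np.ndarray, lam: float) -> np.ndarray:
    lam = max(float(lam), 1e-12)
    return k * np.log(lam) - lam - gammaln(k + 1.0)


def to_counts(image: np.ndarray, max_count: int = 255) -> np.ndarray:
    """Coerce an image to nonnegative integer counts.

    Integer-valued images are used as is; everything else is affinely rescaled
    onto [0, max_count] and rounded, since the Poisson likelihood needs
    counts.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if np.any(image < 0):
        raise ValueError("pixel values must be nonnegative")
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.int64)
    if np.allclose(image, np.round(image)):
        return np.round(image).astype(np.int64)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros(image.shape, np.int64)
    return np.round((image - lo) / (hi - lo) * max_count).astype(np.int64)


class PoissonMixture:
    """Two-component Poisson mixture estimator for count images.

    Parameters
    ----------
    max_iter : maximum number of EM iterations.
    tol : absolute log-likelihood change below which EM is declared converged.

    ``fit`` returns a :class:`PoissonMixtureFit`; a constant image yields a
    degenerate fit (``rate_low == rate_high``) flagged as such rather than an
    error, so callers can decide how to treat contrast-free images.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, image: np.ndarray) -> PoissonMixtureFit:
        counts = to_counts(image)
        values, weights = np.unique(counts.ravel(), return_counts=True)
        values = values.astype(float)
        n = weights.sum()

        if len(values) == 1:
            v = float(values[0])
            ll = float((weights * _poisson_logpmf(values, v)).sum())
            return PoissonMixtureFit(rate_low=v, rate_high=v, weight_high=0.5,
                                     log_likelihood=ll, n_iterations=0,
                                     converged=True, degenerate=True,
                                     log_likelihood_trace=np.array([ll]))

        # moment-style init from the lower/upper halves of the distribution
        order = np.argsort(values)
        cum = np.cumsum(weights[order]) / n
        split = values[order][np.searchsorted(cum, 0.5)]
        lo_mask = values <= split
        w_lo = weights[lo_mask].sum()
        lam_lo = float((values[lo_mask] * weights[lo_mask]).sum() / max(w_lo, 1))
        w_hi = n - w_lo
        lam_hi = float((values[~lo_mask] * weights[~lo_mask]).sum() / max(w_hi, 1)) \
            if w_hi else lam_lo * 2 + 1
        lam_lo = max(lam_lo, 1e-3)
        lam_hi = max(lam_hi, lam_lo * 1.001)
        pi_hi = min(max(w_hi / n, 0.05), 0.95)

        trace = []
        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            log_lo = _poisson_logpmf(values, lam_lo) + np.log1p(-pi_hi)
            log_hi = _poisson_logpmf(values, lam_hi) + np.log(max(pi_hi, 1e-300))
            m = np.maximum(log_lo, log_hi)
            denom = m + np.log(np.exp(log_lo - m) + np.exp(log_hi - m))
            ll = float((weights * denom).sum())
            trace.append(ll)
            resp_hi = np.exp(log_hi - denom)

            wh = (weights * resp_hi).sum()
            wl = n - wh
            lam_hi_new = (weights * resp_hi * values).sum() / max(wh, 1e-12)
            lam_lo_new = (weights * (1 - resp_hi) * values).sum() / max(wl, 1e-12)
            pi_hi = min(max(wh / n, 1e-9), 1 - 1e-9)
            lam_lo, lam_hi = lam_lo_new, lam_hi_new

            if abs(ll - prev_ll) < self.tol:
                converged = True
                break
            prev_ll = ll

        if lam_lo > lam_hi:  # order components by rate
            lam_lo, lam_hi = lam_hi, lam_lo
            pi_hi = 1.0 - pi_hi
        degenerate = (lam_hi - lam_lo) < 1e-6 * max(lam_hi, 1.0)
        return PoissonMixtureFit(rate_low=float(lam_lo), rate_high=float(lam_hi),
                                 weight_high=float(pi_hi),
                                 log_likelihood=float(trace[-1]),
                                 n_iterations=it, converged=converged,
                                 degenerate=degenerate,
                                 log_likelihood_trace=np.array(trace))


def fit_poisson_mixture(image: np.ndarray, max_iter: int = 200,
                        tol: float = 1e-6) -> PoissonMixtureFit:
    """Fit the two-component Poisson mixture to an image by EM."""
    return PoissonMixture(max_iter=max_iter, tol=tol).fit(image)


def segment_squares(image: np.ndarray, fit: PoissonMixtureFit) -> SegmentationMask:
    """Classify each pixel by posterior under the fitted mixture.

    A pixel is marked square-class iff its posterior responsibility under the
    high-rate component is >= 0.5 (ties go to the bright component, favouring
    recall at the localization stage).
    """
    if fit.degenerate:
        raise DegenerateMixtureError(
            "cannot segment: mixture fit is degenerate (constant image?)"
        )
    counts = to_counts(image)
    post = fit.posterior_high(counts.astype(float))
    return SegmentationMask(mask=post >= 0.5)
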