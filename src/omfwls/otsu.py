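"""Otsu thresholding of continuous detection scores.

Scores on valid pixels are quantized to L grayscale levels over their
[min, max] range; an exhaustive scan over thresholds 0 < T < L-1 maximizes
the between-class variance

    sigma^2(T) = p1 (m1 - G)^2 + p2 (m2 - G)^2 = p1 p2 (m1 - m2)^2

where p1, m1 are the proportion and mean level of pixels at levels <= T,
p2, m2 those above, and G = p1 m1 + p2 m2 the global mean. The decomposed
and product forms of sigma^2 are algebraically identical; both are exposed
for cross-checking.
Ties break toward the smallest T. The target class is the high-score class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .omf import DetectionMap
from .raster_io import BinaryMask

__all__ = ["OtsuResult", "otsu_threshold", "apply_threshold",
           "between_class_variance_curve"]


@dataclass
class OtsuResult:
    threshold_level: int          # T* in [1, L-2]
    threshold_value: float        # level boundary mapped back to score units
    sigma2_curve: np.ndarray      # between-class variance per candidate T
    p1: float
    p2: float
    m1: float
    m2: float
    G: float
    n_levels: int
    score_range: tuple[float, float]


def _quantize(values: np.ndarray, lo: float, hi: float, n_levels: int) -> np.ndarray:
    q = np.rint((values - lo) / (hi - lo) * (n_levels - 1))
    return q.astype(np.int64)


def between_class_variance_curve(hist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """sigma^2(T) for T = 0..L-1 from a histogram, in both equivalent forms.

    Class 1 = levels <= T, class 2 = levels > T. Entries where either class
    is empty are 0. Returns (decomposed form, product form); they agree to
    rounding error.
    """
    hist = np.asarray(hist, dtype=np.float64)
    L = hist.size
    levels = np.arange(L, dtype=np.float64)
    p = hist / hist.sum()
    p1 = np.cumsum(p)
    p2 = 1.0 - p1
    cum_m = np.cumsum(p * levels)
    G = cum_m[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.where(p1 > 0, cum_m / p1, 0.0)
        m2 = np.where(p2 > 0, (G - cum_m) / p2, 0.0)
    both = (p1 > 0) & (p2 > 0)
    decomposed = np.where(both, p1 * (m1 - G) ** 2 + p2 * (m2 - G) ** 2, 0.0)
    product = np.where(both, p1 * p2 * (m1 - m2) ** 2, 0.0)
    return decomposed, product


def otsu_threshold(dmap: DetectionMap, n_levels: int = 256) -> OtsuResult:
    """Between-class-variance-maximizing threshold of a detection map.

    Requires at least two distinct score values among valid pixels.
    """
    v = dmap.valid_scores
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ValueError("cannot threshold a constant detection map")
    q = _quantize(v, lo, hi, n_levels)
    hist = np.bincount(q, minlength=n_levels).astype(np.float64)
    sigma2, _ = between_class_variance_curve(hist)
    # T must leave both classes non-empty: scan 0 < T < L-1
    interior = sigma2.copy()
    interior[0] = interior[-1] = -np.inf
    T = int(np.argmax(interior))  # argmax takes the smallest index on ties

    levels = np.arange(n_levels, dtype=np.float64)
    p = hist / hist.sum()
    p1 = float(p[: T + 1].sum())
    p2 = 1.0 - p1
    m1 = float((p[: T + 1] * levels[: T + 1]).sum() / p1)
    m2 = float((p[T + 1:] * levels[T + 1:]).sum() / p2)
    G = float((p * levels).sum())
    # boundary between level T and T+1, back in score units
    value = lo + (T + 0.5) / (n_levels - 1) * (hi - lo)
    return OtsuResult(T, value, sigma2, p1, p2, m1, m2, G, n_levels, (lo, hi))


def apply_threshold(dmap: DetectionMap, result: OtsuResult) -> BinaryMask:
    """Binarize: valid pixels scoring above the threshold become target (1)."""
    mask = (dmap.scores > result.threshold_value) & dmap.valid_mask
    return BinaryMask(mask, dict(dmap.geo_meta))
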