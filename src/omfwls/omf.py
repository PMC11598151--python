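"""Matched-filter detectors: classic MF and the whitened orthogonal MF (OMF).

The classic matched filter maximizes target response subject to the unit-gain
constraint w^T (mu1 - mu0) = 1:

    w = S^{-1} (mu1 - mu0) / ((mu1 - mu0)^T S^{-1} (mu1 - mu0))
    y_MF(x) = (x - mu0)^T S^{-1} (mu1 - mu0) / ((mu1 - mu0)^T S^{-1} (mu1 - mu0))

so y_MF(mu0) = 0 and y_MF(mu1) = 1.

The OMF operates in whitened space, where the background covariance is
(approximately) the identity: pixels are whitened, the target spectrum is
whitened and projected onto the orthogonal complement of the whitened
background endmembers, and the score is the dot product with the normalized
projected direction:

    v = P_Uperp d_white,  w = v / ||v||,  y_OMF(s) = w^T x_white,s

``project_target`` selects between two readings of the filter direction.
The default (False) normalizes the unprojected whitened target, the form
the constrained minimization actually yields in whitened space, where the
whitening itself already decorrelates the background. With
``project_target=True`` the OSP projection is applied to the target before
normalization, which actively annihilates the supplied background
endmembers — but when those endmembers span most of the whitened
class-structure subspace, it annihilates the target signature along with
them, so it should be used only with endmembers well separated from the
target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .osp import Projector
from .whitening import DEFAULT_EPSILON, WhiteningModel, whiten_pixels

__all__ = [
    "MatchedFilterModel",
    "DetectionMap",
    "fit_classic_mf",
    "score_classic_mf",
    "score_omf",
    "omf_filter_vector",
    "rescale_scores",
]


@dataclass
class MatchedFilterModel:
    mu0: np.ndarray          # background mean
    mu1: np.ndarray          # target mean
    sigma: np.ndarray        # background covariance
    w: np.ndarray            # filter satisfying w^T (mu1 - mu0) = 1


@dataclass
class DetectionMap:
    """Single-band continuous score image."""

    scores: np.ndarray
    kind: str = "omf"        # one of {mf, omf, omf_wls}
    valid_mask: np.ndarray | None = None   # True = pixel participates
    scaling: tuple[float, float] | None = None  # (min, max) used by rescale
    geo_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.scores.shape, dtype=bool)
        if not np.all(np.isfinite(self.scores[self.valid_mask])):
            raise ValueError("non-finite scores on valid pixels")

    @property
    def valid_scores(self) -> np.ndarray:
        return self.scores[self.valid_mask]


def fit_classic_mf(
    X: np.ndarray,
    target_spectra: np.ndarray,
    background_mask: np.ndarray | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> MatchedFilterModel:
    """Fit the classic matched filter on a (bands x pixels) matrix.

    ``target_spectra`` is an (n, B) stack averaged into mu1; mu0 and the
    covariance come from the background pixels (all pixels when no mask is
    given). The covariance is ridge-regularized by ``epsilon * I`` when
    near-singular.
    """
    X = np.asarray(X, dtype=np.float64)
    B, S = X.shape
    t = np.atleast_2d(np.asarray(target_spectra, dtype=np.float64))
    if t.shape[0] == 0:
        raise ValueError("at least one target spectrum is required")
    mu1 = t.mean(axis=0)
    bg = X if background_mask is None else X[:, background_mask]
    if bg.shape[1] < B + 1:
        raise ValueError(f"need at least {B + 1} background pixels, got {bg.shape[1]}")
    mu0 = bg.mean(axis=1)
    Xc = bg - mu0[:, None]
    sigma = (Xc @ Xc.T) / bg.shape[1]
    delta = mu1 - mu0
    if np.linalg.norm(delta) < 1e-12:
        raise ValueError("target and background means coincide: zero contrast")
    if np.linalg.cond(sigma) > 1e10:
        sigma = sigma + epsilon * np.eye(B)
    sol = np.linalg.solve(sigma, delta)
    denom = float(delta @ sol)
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError("covariance is singular even after regularization")
    return MatchedFilterModel(mu0, mu1, sigma, sol / denom)


def score_classic_mf(model: MatchedFilterModel, X: np.ndarray) -> DetectionMap:
    """Per-pixel MF score; affine in x with score(mu0)=0, score(mu1)=1."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != model.w.size:
        raise ValueError("band count mismatch between model and data")
    scores = model.w @ (X - model.mu0[:, None])
    return DetectionMap(scores, kind="mf")


def omf_filter_vector(
    d_white: np.ndarray, projector: Projector, project_target: bool = False
) -> np.ndarray:
    """Unit-norm OMF filter direction w from the whitened target and projector."""
    d_white = np.asarray(d_white, dtype=np.float64)
    v = projector @ d_white if project_target else d_white
    nv = np.linalg.norm(v)
    if nv < 1e-10:
        raise ValueError(
            "degenerate target: whitened target spectrum is annihilated by the "
            "background projector"
        )
    return v / nv


def score_omf(
    model: WhiteningModel,
    d_white: np.ndarray,
    projector: Projector,
    X: np.ndarray,
    project_target: bool = False,
) -> DetectionMap:
    """Whitened orthogonal matched-filter scores for a (bands x pixels) matrix."""
    w = omf_filter_vector(d_white, projector, project_target)
    Xw = whiten_pixels(model, X)
    return DetectionMap(w @ Xw, kind="omf")


def rescale_scores(dmap: DetectionMap) -> DetectionMap:
    """Min-max rescale valid scores to [0, 1] (grayscale mapping for WLS/Otsu).

    A constant map rescales to 0.5 everywhere with a warning. The (min, max)
    used is recorded on the result.
    """
    v = dmap.valid_scores
    lo, hi = float(v.min()), float(v.max())
    out = np.zeros_like(dmap.scores)
    if hi == lo:
        warnings.warn("constant detection map: rescaled to 0.5 everywhere", stacklevel=2)
        out[dmap.valid_mask] = 0.5
    else:
        out[dmap.valid_mask] = (v - lo) / (hi - lo)
    return DetectionMap(out, dmap.kind, dmap.valid_mask.copy(), (lo, hi), dict(dmap.geo_meta))
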