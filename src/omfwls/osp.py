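"""Orthogonal subspace projection onto the background's orthogonal complement.

Under the linear mixing model x = d*a_d + U*a_U + n (target spectrum d,
background endmembers as columns of U), the projector

    P = I - U (U^T U)^{-1} U^T

annihilates everything in span(U); P d is then the detector direction with
the background suppressed. The inverse is never formed explicitly: P x is
computed via a least-squares residual map (QR under the hood), which is the
same operator with better conditioning.

The whitened variant first maps d and U through a fitted whitening model so
the projection happens in the decorrelated space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .whitening import WhiteningModel, whiten_spectrum

__all__ = ["MixingModel", "Projector", "build_projector", "whitened_projector",
           "auto_background_endmembers"]

_COND_LIMIT = 1e10


@dataclass
class MixingModel:
    """Linear mixing of a target spectrum with background endmembers.

    Abundances, when supplied, must be non-negative and sum to one; they are
    stored for bookkeeping and not used by the detector itself.
    """

    d: np.ndarray
    U: np.ndarray
    alpha_d: float | None = None
    alpha_U: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64).reshape(self.d.size, -1)
        if self.alpha_d is not None and self.alpha_U is not None:
            a = np.concatenate([[self.alpha_d], np.atleast_1d(self.alpha_U)])
            if np.any(a < 0) or not np.isclose(a.sum(), 1.0):
                raise ValueError("abundances must be non-negative and sum to 1")

    @property
    def n_endmembers(self) -> int:
        """K = target + background endmember count."""
        return 1 + self.U.shape[1]


@dataclass
class Projector:
    """Orthogonal projector P annihilating the columns of ``basis``."""

    P: np.ndarray
    basis: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __matmul__(self, x):
        return self.P @ x


def build_projector(U: np.ndarray) -> Projector:
    """P = I - U (U^T U)^{-1} U^T; the identity when U has no columns.

    Raises for rank-deficient U (condition number above 1e10), since the
    pseudo-inverse is then ill-defined for background annihilation.
    """
    U = np.asarray(U, dtype=np.float64)
    if U.ndim == 1:
        U = U[:, None]
    L, m = U.shape
    if m == 0:
        return Projector(np.eye(L), U)
    sv = np.linalg.svd(U, compute_uv=False)
    if sv[-1] == 0 or sv[0] / sv[-1] > _COND_LIMIT:
        raise ValueError(
            f"background endmember matrix is rank-deficient "
            f"(condition number {np.inf if sv[-1] == 0 else sv[0] / sv[-1]:.2e}); "
            f"remove collinear columns (have {m} columns of length {L})"
        )
    Q, _ = np.linalg.qr(U)  # orthonormal basis of span(U)
    P = np.eye(L) - Q @ Q.T
    return Projector(P, U)


def whitened_projector(
    model: WhiteningModel, d: np.ndarray, U: np.ndarray | None
) -> tuple[Projector, np.ndarray]:
    """Whiten d and the endmembers, then build the projector in whitened space.

    Returns (projector on whitened background, whitened target spectrum).
    Warns when the whitened target is (numerically) inside the background
    span, since the projected detector direction then vanishes.
    """
    d_white = whiten_spectrum(model, d)
    if U is None or np.size(U) == 0:
        proj = Projector(np.eye(model.n_bands), np.empty((model.n_bands, 0)))
    else:
        U = np.asarray(U, dtype=np.float64).reshape(model.n_bands, -1)
        U_white = np.column_stack([whiten_spectrum(model, U[:, j]) for j in range(U.shape[1])])
        proj = build_projector(U_white)
    if np.linalg.norm(proj @ d_white) < 1e-8 * max(np.linalg.norm(d_white), 1.0):
        warnings.warn(
            "whitened target spectrum lies in the background span; the OSP-"
            "projected detector direction is degenerate",
            stacklevel=2,
        )
    return proj, d_white


def auto_background_endmembers(
    X_white: np.ndarray, ndvi_flat: np.ndarray, n_endmembers: int = 2
) -> np.ndarray:
    """Heuristic background endmembers when no library spectra are given.

    Takes pixels at or below the scene's NDVI median as background and returns
    the leading ``n_endmembers`` eigenvectors of their whitened covariance
    (columns). This is a convenience default, not an endmember-extraction
    algorithm.
    """
    bg = X_white[:, ndvi_flat <= np.median(ndvi_flat)]
    if bg.shape[1] < X_white.shape[0]:
        raise ValueError("too few background pixels for automatic endmembers")
    C = np.cov(bg)
    vals, vecs = np.linalg.eigh(C)
    return vecs[:, np.argsort(vals)[::-1][:n_endmembers]]
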