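"""Edge-preserving weighted-least-squares smoothing of a score map.

Minimizes

    (u - y)^T (u - y) + lambda * (u^T Dx^T Ax Dx u + u^T Dy^T Ay Dy u)

whose unique minimizer solves the sparse SPD system (I + lambda * L) u = y
with L = Dx^T Ax Dx + Dy^T Ay Dy. Dx, Dy are forward-difference operators
with replicate (Neumann) boundaries — their border rows are zero, so L
annihilates constant images. Ax, Ay are diagonal gradient-adaptive weights
computed on the guide image (the score map itself):

    a = (|gradient|^alpha + eps_w)^{-1}

Large gradients get small weights, so smoothing is suppressed across edges
while flat regions are averaged hard; this is the standard edge-preserving
WLS weighting. Defaults: lambda = 1.0, alpha = 1.2, eps_w = 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .omf import DetectionMap

__all__ = ["WlsParams", "WlsSystem", "build_weights", "build_system", "wls_filter",
           "wls_objective"]


@dataclass
class WlsParams:
    lam: float = 1.0      # smoothing strength lambda
    alpha: float = 1.2    # gradient sensitivity exponent
    eps_w: float = 1e-4   # weight floor

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.alpha <= 0 or self.eps_w <= 0:
            raise ValueError("alpha and eps_w must be positive")


@dataclass
class WlsSystem:
    Dx: sp.spmatrix
    Dy: sp.spmatrix
    Ax: sp.spmatrix
    Ay: sp.spmatrix

    @property
    def laplacian(self) -> sp.spmatrix:
        return self.Dx.T @ self.Ax @ self.Dx + self.Dy.T @ self.Ay @ self.Dy


def _diff_ops(rows: int, cols: int) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Forward-difference operators (S x S) in row-major layout, zero at borders."""
    S = rows * cols
    idx = np.arange(S).reshape(rows, cols)
    # d/dx: u[r, c+1] - u[r, c], zero on the last column
    src = idx[:, :-1].ravel()
    dst = idx[:, 1:].ravel()
    data = np.concatenate([-np.ones(src.size), np.ones(src.size)])
    Dx = sp.csr_matrix(
        (data, (np.concatenate([src, src]), np.concatenate([src, dst]))), shape=(S, S)
    )
    # d/dy: u[r+1, c] - u[r, c], zero on the last row
    src = idx[:-1, :].ravel()
    dst = idx[1:, :].ravel()
    data = np.concatenate([-np.ones(src.size), np.ones(src.size)])
    Dy = sp.csr_matrix(
        (data, (np.concatenate([src, src]), np.concatenate([src, dst]))), shape=(S, S)
    )
    return Dx, Dy


def build_weights(y: np.ndarray, params: WlsParams) -> tuple[np.ndarray, np.ndarray]:
    """Gradient-adaptive diagonal weights on the guide image y (rows x cols).

    Returns flat (S,) weight vectors for the x and y difference directions;
    border positions (where the forward difference is zero) get weight 0 so
    they contribute nothing to the penalty.
    """
    y = np.asarray(y, dtype=np.float64)
    gx = np.zeros_like(y)
    gx[:, :-1] = y[:, 1:] - y[:, :-1]
    gy = np.zeros_like(y)
    gy[:-1, :] = y[1:, :] - y[:-1, :]
    ax = 1.0 / (np.abs(gx) ** params.alpha + params.eps_w)
    ay = 1.0 / (np.abs(gy) ** params.alpha + params.eps_w)
    ax[:, -1] = 0.0
    ay[-1, :] = 0.0
    return ax.ravel(), ay.ravel()


def build_system(y: np.ndarray, params: WlsParams) -> WlsSystem:
    rows, cols = y.shape
    Dx, Dy = _diff_ops(rows, cols)
    ax, ay = build_weights(y, params)
    return WlsSystem(Dx, Dy, sp.diags(ax), sp.diags(ay))


def wls_objective(u: np.ndarray, y: np.ndarray, system: WlsSystem, lam: float) -> float:
    """The quadratic energy the filter minimizes (u, y flat or 2-D)."""
    u, y = np.ravel(u), np.ravel(y)
    r = u - y
    dx, dy = system.Dx @ u, system.Dy @ u
    return float(r @ r + lam * (dx @ (system.Ax @ dx) + dy @ (system.Ay @ dy)))


def wls_filter(dmap: DetectionMap, params: WlsParams | None = None) -> DetectionMap:
    """Solve (I + lambda L) u = y and return the smoothed detection map.

    Expects scores rescaled to [0, 1]. Invalid (nodata) pixels are filled
    with the valid-pixel mean for the solve and keep their invalid flag.
    Output is clipped back to [0, 1] only when numerically outside by < 1e-6.
    """
    params = params or WlsParams()
    y = dmap.scores.astype(np.float64).copy()
    if not dmap.valid_mask.all():
        y[~dmap.valid_mask] = y[dmap.valid_mask].mean()
    if params.lam == 0:
        return DetectionMap(dmap.scores.copy(), "omf_wls", dmap.valid_mask.copy(),
                            dmap.scaling, dict(dmap.geo_meta))
    system = build_system(y, params)
    A = (sp.identity(y.size, format="csr") + params.lam * system.laplacian).tocsc()
    u = spla.spsolve(A, y.ravel())
    resid = np.linalg.norm(A @ u - y.ravel()) / max(np.linalg.norm(y), 1e-300)
    if resid > 1e-8:
        raise RuntimeError(f"WLS solve did not converge: relative residual {resid:.2e}")
    u = u.reshape(y.shape)
    low, high = u.min(), u.max()
    if low > -1e-6 and high < 1 + 1e-6:
        u = np.clip(u, 0.0, 1.0)
    return DetectionMap(u, "omf_wls", dmap.valid_mask.copy(), dmap.scaling,
                        dict(dmap.geo_meta))
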