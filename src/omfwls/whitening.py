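"""Regularized PCA whitening of flattened pixel matrices.

Pipeline: per-band min-max normalization to [0, 1], mean centering,
covariance C = (1/n) X X^T, symmetric eigendecomposition C = U L U^T, then
per-component scaling x_pca,i = x_rot,i / sqrt(lambda_i + eps). The small
regularizer eps (default 1e-5) keeps near-zero eigenvalues from blowing up
the scaling; constant bands therefore whiten to (near) zero instead of NaN.

The fitted model is an affine map; it applies identically to image pixels
and to library spectra, so target/background spectra can be carried into
the whitened space where the background covariance is (approximately) the
identity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["WhiteningModel", "fit_whitening", "whiten_pixels", "whiten_spectrum"]

DEFAULT_EPSILON = 1e-5


@dataclass
class WhiteningModel:
    """Fitted normalization + centering + regularized eigen-scaling."""

    band_mins: np.ndarray
    band_maxs: np.ndarray
    mean: np.ndarray          # mean of the normalized data (enforces x-bar = 0)
    eigvecs: np.ndarray       # columns are eigenvectors, descending eigenvalue order
    eigvals: np.ndarray
    epsilon: float
    n_pixels: int

    @property
    def n_bands(self) -> int:
        return self.mean.size

    @property
    def whitening_matrix(self) -> np.ndarray:
        """The explicit linear part diag(1/sqrt(lambda+eps)) U^T."""
        return (self.eigvecs / np.sqrt(self.eigvals + self.epsilon)).T

    def to_json(self, path) -> None:
        obj = {
            "band_mins": self.band_mins.tolist(),
            "band_maxs": self.band_maxs.tolist(),
            "mean": self.mean.tolist(),
            "eigvecs": self.eigvecs.tolist(),
            "eigvals": self.eigvals.tolist(),
            "epsilon": self.epsilon,
            "n_pixels": self.n_pixels,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "WhiteningModel":
        o = json.loads(Path(path).read_text())
        return cls(
            np.asarray(o["band_mins"]), np.asarray(o["band_maxs"]),
            np.asarray(o["mean"]), np.asarray(o["eigvecs"]),
            np.asarray(o["eigvals"]), float(o["epsilon"]), int(o["n_pixels"]),
        )


def _normalize(model: WhiteningModel, X: np.ndarray) -> np.ndarray:
    span = model.band_maxs - model.band_mins
    out = np.zeros_like(X, dtype=np.float64)
    nz = span != 0
    out[nz] = (X[nz] - model.band_mins[nz, None]) / span[nz, None]
    return out


def fit_whitening(X: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> WhiteningModel:
    """Fit the whitening transform on a (bands x pixels) matrix of valid pixels.

    Eigenvalues are sorted descending; each eigenvector's sign is fixed so its
    largest-magnitude component is positive, making the basis deterministic.
    """
    X = np.asarray(X, dtype=np.float64)
    B, S = X.shape
    if S < 2:
        raise ValueError(f"need at least 2 pixels to fit whitening, got {S}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    mins, maxs = X.min(axis=1), X.max(axis=1)
    if np.any(mins == maxs):
        warnings.warn(
            "constant band(s) found during whitening fit; they normalize to 0 "
            "and their eigenvalues are absorbed by the regularizer",
            stacklevel=2,
        )
    model = WhiteningModel(mins, maxs, np.zeros(B), np.eye(B), np.ones(B), epsilon, S)
    Xn = _normalize(model, X)
    model.mean = Xn.mean(axis=1)
    Xc = Xn - model.mean[:, None]
    C = (Xc @ Xc.T) / S
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    # deterministic sign convention
    flips = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(B)])
    flips[flips == 0] = 1.0
    model.eigvecs = vecs * flips
    model.eigvals = vals
    return model


def whiten_pixels(model: WhiteningModel, X: np.ndarray) -> np.ndarray:
    """Apply the fitted transform to a (bands x pixels) matrix."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != model.n_bands:
        raise ValueError(f"matrix has {X.shape[0]} rows, model expects {model.n_bands}")
    Xc = _normalize(model, X) - model.mean[:, None]
    Xrot = model.eigvecs.T @ Xc
    return Xrot / np.sqrt(model.eigvals + model.epsilon)[:, None]


def whiten_spectrum(model: WhiteningModel, s: np.ndarray) -> np.ndarray:
    """Whiten a single spectrum (length-B vector)."""
    s = np.asarray(s, dtype=np.float64)
    if s.shape != (model.n_bands,):
        raise ValueError(f"spectrum has length {s.size}, model expects {model.n_bands}")
    return whiten_pixels(model, s[:, None])[:, 0]
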