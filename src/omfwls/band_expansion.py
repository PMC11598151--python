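"""Band expansion: derived spectral indices stacked onto the raw bands.

Four feature indices sharpen target/background separability before
whitening: NDVI and EVI (vegetation), NDWI (water) and a suspended-matter
index TSM. Expanding a blue/green/red/nir scene yields an 8-band cube.

Index formulas (B1 = blue, B2 = green, B3 = red, B4 = nir):

    NDVI = (B4 - B3) / (B4 + B3)
    EVI  = 2.5 (B4 - B3) / (B4 + 6 B3 - 7.5 B2 + 1)
    NDWI = (B2 - B4) / (B2 + B4)
    TSM  = 0.028 B1 + 0.019 B2 - 5.31 (B2 / B1) + 0.537

Note the EVI here uses the green band in its soil/aerosol term (canonical
EVI uses blue); TSM's third term is a green/blue ratio by default, with a
``tsm_product`` switch for the literal-product reading. Pixels where a
denominator vanishes are set to 0 and flagged invalid rather than NaN, so
downstream covariance estimates stay finite.
"""

from __future__ import annotations

import numpy as np

from .raster_io import MultispectralCube, RAW_ROLES

__all__ = ["ndvi", "evi", "ndwi", "tsm", "expand_bands", "INDEX_ROLES"]

INDEX_ROLES = ("ndvi", "evi", "ndwi", "tsm")


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """num/den with zero-denominator pixels -> 0 and a validity mask."""
    valid = den != 0
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape), dtype=np.float64)
    np.divide(num, den, out=out, where=valid)
    return out, valid


def ndvi(cube: MultispectralCube) -> tuple[np.ndarray, np.ndarray]:
    """Normalized difference vegetation index (nir - red)/(nir + red)."""
    r, n = cube.band("red"), cube.band("nir")
    return _safe_ratio(n - r, n + r)


def evi(cube: MultispectralCube) -> tuple[np.ndarray, np.ndarray]:
    """Enhanced vegetation index, green-band variant."""
    g, r, n = cube.band("green"), cube.band("red"), cube.band("nir")
    return _safe_ratio(2.5 * (n - r), n + 6.0 * r - 7.5 * g + 1.0)


def ndwi(cube: MultispectralCube) -> tuple[np.ndarray, np.ndarray]:
    """Normalized difference water index (green - nir)/(green + nir)."""
    g, n = cube.band("green"), cube.band("nir")
    return _safe_ratio(g - n, g + n)


def tsm(cube: MultispectralCube, product: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Total suspended matter index.

    ``product=True`` multiplies green by blue in the third term instead of
    dividing (the alternative reading of the juxtaposed coefficient).
    """
    b, g = cube.band("blue"), cube.band("green")
    if product:
        term = 5.31 * g * b
        valid = np.ones_like(b, dtype=bool)
    else:
        term, valid = _safe_ratio(5.31 * g, b)
    out = 0.028 * b + 0.019 * g - term + 0.537
    out[~valid] = 0.0
    return out, valid


def expand_bands(cube: MultispectralCube, tsm_product: bool = False) -> MultispectralCube:
    """Stack [blue, green, red, nir, ndvi, evi, ndwi, tsm] into an 8-band cube.

    Pixels where any index denominator vanished are merged into the output
    nodata mask.
    """
    if cube.n_bands != 4:
        raise ValueError(f"expected a 4-band cube with roles {RAW_ROLES}, got {cube.n_bands} bands")
    for role in RAW_ROLES:
        cube.band(role)  # raises KeyError with a useful message if absent
    layers, valid = [], np.ones(cube.shape, dtype=bool)
    for fn in (ndvi, evi, ndwi):
        img, v = fn(cube)
        layers.append(img)
        valid &= v
    img, v = tsm(cube, product=tsm_product)
    layers.append(img)
    valid &= v
    data = np.concatenate([cube.data, np.stack(layers)])
    mask = cube.nodata_mask | ~valid
    data[:, mask] = 0.0
    return MultispectralCube(
        data, tuple(cube.band_roles) + INDEX_ROLES, mask, dict(cube.geo_meta)
    )
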