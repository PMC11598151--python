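"""Multispectral raster and spectral-library I/O.

Containers and file formats shared by every pipeline stage. A scene is a
band-major cube (bands x rows x cols) with explicit band roles and a nodata
mask; spectra live in a small CSV-backed library. Rasters are stored as
multiband float32 TIFF with a JSON ImageDescription (band roles, nodata
value, opaque geo metadata), or as ENVI rasters (plain-text ``.hdr`` plus a
raw binary cube, interleave bsq/bil/bip).

Conventions every downstream stage relies on:

* 0-based, row-major pixel indexing; the flat index of pixel (r, c) in a
  rows x cols image is ``s = r * cols + c``.
* nodata pixels are excluded from all statistics, never zero-filled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "MultispectralCube",
    "SpectralLibrary",
    "BinaryMask",
    "flatten",
    "unflatten",
    "read_cube",
    "write_cube",
    "read_spectral_library",
    "write_spectral_library",
    "read_mask",
    "write_mask",
]

DEFAULT_NODATA = -9999.0

#: canonical role order of a 4-band input scene
RAW_ROLES = ("blue", "green", "red", "nir")


@dataclass
class MultispectralCube:
    """A bands x rows x cols raster with named band roles.

    ``nodata_mask`` is True at excluded pixels (e.g. sea-masked areas);
    ``geo_meta`` is an opaque dict preserved verbatim on write.
    """

    data: np.ndarray
    band_roles: tuple[str, ...]
    nodata_mask: np.ndarray | None = None
    geo_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D (bands, rows, cols), got {self.data.ndim}-D")
        self.band_roles = tuple(self.band_roles)
        if len(self.band_roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.band_roles)} band roles for {self.data.shape[0]} bands"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.data.shape[1:], dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.data.shape[1:]:
                raise ValueError("nodata_mask shape does not match raster shape")
        valid = self.data[:, ~self.nodata_mask]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("non-finite values outside the nodata mask")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def band(self, role: str) -> np.ndarray:
        """Return the 2-D raster of the band with the given role."""
        try:
            i = self.band_roles.index(role)
        except ValueError:
            raise KeyError(f"cube has no band with role {role!r}; roles: {self.band_roles}")
        return self.data[i]


@dataclass
class SpectralLibrary:
    """Named spectra (target samples and background endmembers)."""

    entries: list[tuple[str, np.ndarray, str]]
    band_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        self.band_roles = tuple(self.band_roles)
        B = len(self.band_roles)
        cleaned = []
        for name, spec, role in self.entries:
            spec = np.asarray(spec, dtype=np.float64)
            if spec.shape != (B,):
                raise ValueError(f"spectrum {name!r} has length {spec.size}, expected {B}")
            if role not in ("target", "background"):
                raise ValueError(f"unknown role {role!r} for spectrum {name!r}")
            cleaned.append((name, spec, role))
        self.entries = cleaned

    def spectra(self, role: str) -> np.ndarray:
        """All spectra with the given role, stacked as an (n, B) array."""
        rows = [s for _, s, r in self.entries if r == role]
        if not rows:
            return np.empty((0, len(self.band_roles)))
        return np.stack(rows)

    @property
    def target_mean(self) -> np.ndarray:
        """Average target spectrum (the detector's prior d)."""
        t = self.spectra("target")
        if t.shape[0] == 0:
            raise ValueError("library has no target spectra")
        return t.mean(axis=0)

    @property
    def background_matrix(self) -> np.ndarray:
        """Background endmembers as columns of a (B, m) matrix."""
        return self.spectra("background").T


@dataclass
class BinaryMask:
    """Boolean rows x cols raster (True = target)."""

    data: np.ndarray
    geo_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2-D")


# ---------------------------------------------------------------------------
# flattening

def flatten(cube: MultispectralCube) -> tuple[np.ndarray, tuple[int, int]]:
    """Rearrange the cube into a (bands x pixels) matrix.

    Pixel (r, c) maps to column ``s = r * cols + c``. Returns the matrix and
    the (rows, cols) shape needed to invert the layout.
    """
    B, rows, cols = cube.data.shape
    return cube.data.reshape(B, rows * cols), (rows, cols)


def unflatten(X: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`flatten` for a (B, S) matrix or an (S,) score vector."""
    rows, cols = shape
    X = np.asarray(X)
    if X.ndim == 1:
        return X.reshape(rows, cols)
    return X.reshape(X.shape[0], rows, cols)


# ---------------------------------------------------------------------------
# TIFF / ENVI raster I/O

def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower() == "envi":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key = key.strip().lower()
            buf = val.strip()
        else:
            buf += " " + line
        if buf.count("{") == buf.count("}"):
            fields[key] = buf.strip().strip("{}").strip()
            key, buf = None, ""
    return fields


_ENVI_DTYPES = {"1": np.uint8, "2": np.int16, "4": np.float32, "5": np.float64, "12": np.uint16}
_ENVI_CODES = {np.dtype(np.uint8): 1, np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _read_envi(path: Path, band_roles) -> MultispectralCube:
    hdr = path.with_suffix(path.suffix + ".hdr")
    if not hdr.exists():
        hdr = path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    f = _parse_envi_header(hdr)
    rows, cols, bands = int(f["lines"]), int(f["samples"]), int(f["bands"])
    dtype = _ENVI_DTYPES[f.get("data type", "4")]
    interleave = f.get("interleave", "bsq").lower()
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise ValueError(f"ENVI file size mismatch: {raw.size} values for {bands}x{rows}x{cols}")
    if interleave == "bsq":
        data = raw.reshape(bands, rows, cols)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(1, 0, 2)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands).transpose(2, 0, 1)
    else:
        raise ValueError(f"unknown ENVI interleave {interleave!r}")
    data = data.astype(np.float64)
    nodata = float(f["data ignore value"]) if "data ignore value" in f else None
    roles = band_roles
    if roles is None and "band names" in f:
        roles = tuple(s.strip() for s in f["band names"].split(","))
    return _assemble_cube(data, roles, nodata, {})


def _assemble_cube(data, band_roles, nodata, geo_meta) -> MultispectralCube:
    B = data.shape[0]
    if band_roles is None:
        band_roles = tuple(f"band_{i + 1}" for i in range(B))
    if len(band_roles) != B:
        raise ValueError(f"{len(band_roles)} band roles supplied for a {B}-band file")
    if nodata is None:
        mask = ~np.isfinite(data).all(axis=0)
    else:
        mask = (data == nodata).any(axis=0) | ~np.isfinite(data).all(axis=0)
    data = data.copy()
    data[:, mask] = 0.0
    return MultispectralCube(data, band_roles, mask, dict(geo_meta))


def read_cube(path, band_roles=None) -> MultispectralCube:
    """Read a multiband TIFF or ENVI raster into a :class:`MultispectralCube`.

    Bands keep file order unless ``band_roles`` relabels them. Nodata values
    recorded in the file populate the cube's nodata mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = {}
        if data.ndim == 2:
            data = data[None]
        data = np.asarray(data, dtype=np.float64)
        roles = band_roles
        if roles is None and "band_roles" in meta:
            roles = tuple(meta["band_roles"])
        return _assemble_cube(data, roles, meta.get("nodata"), meta.get("geo_meta", {}))
    return _read_envi(path, band_roles)


def write_cube(cube: MultispectralCube, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a cube as float32 multiband TIFF (or ENVI if ``path`` ends in .dat)."""
    path = Path(path)
    data = cube.data.astype(np.float32)
    data[:, cube.nodata_mask] = nodata
    if path.suffix.lower() in (".tif", ".tiff"):
        desc = json.dumps(
            {
                "band_roles": list(cube.band_roles),
                "nodata": nodata if cube.nodata_mask.any() else None,
                "geo_meta": cube.geo_meta,
            }
        )
        tifffile.imwrite(path, data, photometric="minisblack", description=desc)
        return
    # ENVI: raw BSQ cube + text header
    data.tofile(path)
    hdr = path.with_suffix(path.suffix + ".hdr")
    B, rows, cols = data.shape
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {B}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[data.dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "band names = {" + ", ".join(cube.band_roles) + "}",
    ]
    if cube.nodata_mask.any():
        lines.append(f"data ignore value = {nodata}")
    hdr.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# spectral library CSV: name,role,<band>,<band>,...

def read_spectral_library(path) -> SpectralLibrary:
    """Read a spectral library CSV (``name,role,blue,green,red,nir``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[0] == 0 or df.shape[1] < 3:
        raise ValueError(f"spectral library {path} is empty or has no band columns")
    cols = list(df.columns)
    if cols[0].lower() != "name" or cols[1].lower() != "role":
        raise ValueError("library CSV must start with 'name,role' columns")
    band_roles = tuple(cols[2:])
    if df[cols[2:]].isna().any().any():
        raise ValueError("ragged or missing band values in spectral library")
    entries = [
        (str(row[0]), np.asarray(row[2:], dtype=np.float64), str(row[1]).strip().lower())
        for row in df.itertuples(index=False)
    ]
    return SpectralLibrary(entries, band_roles)


def write_spectral_library(lib: SpectralLibrary, path) -> None:
    rows = [
        {"name": n, "role": r, **dict(zip(lib.band_roles, s))}
        for n, s, r in lib.entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# binary masks

def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as 1-band uint8 TIFF (1 = target)."""
    desc = json.dumps({"geo_meta": mask.geo_meta})
    tifffile.imwrite(Path(path), mask.data.astype(np.uint8), description=desc)


def read_mask(path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    geo = {}
    if desc:
        try:
            geo = json.loads(desc).get("geo_meta", {})
        except json.JSONDecodeError:
            pass
    return BinaryMask(data.astype(bool), geo)
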