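"""End-to-end target extraction: expand -> whiten -> project -> score -> WLS -> Otsu.

The full chain, given a 4-band scene and a spectral library:

1. band expansion to the 8-band cube,
2. PCA whitening fitted on valid pixels,
3. whitened OSP projector from the library's background endmembers,
4. OMF scoring (or the classic matched filter as a baseline),
5. min-max rescale, optional edge-preserving WLS smoothing,
6. Otsu binarization, and, when ground truth is given, confusion metrics.

Library spectra are stored on the 4 raw bands; they are lifted to the
expanded 8-band space with the same per-pixel index formulas used on the
image, so the detector prior lives in the same feature space as the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import band_expansion, raster_io
from .band_expansion import expand_bands
from .metrics import ConfusionCounts, confusion
from .omf import (DetectionMap, fit_classic_mf, rescale_scores,
                  score_classic_mf, score_omf)
from .osp import Projector, whitened_projector
from .otsu import OtsuResult, apply_threshold, otsu_threshold
from .raster_io import (BinaryMask, MultispectralCube, SpectralLibrary,
                        flatten, unflatten)
from .whitening import DEFAULT_EPSILON, WhiteningModel, fit_whitening

__all__ = ["PipelineResult", "expand_spectrum", "expand_library", "run_on_arrays"]


def expand_spectrum(spectrum: np.ndarray, tsm_product: bool = False) -> np.ndarray:
    """Lift a 4-band (blue, green, red, nir) spectrum to the 8-band space."""
    spectrum = np.asarray(spectrum, dtype=np.float64)
    cube = MultispectralCube(spectrum.reshape(4, 1, 1), raster_io.RAW_ROLES)
    expanded = expand_bands(cube, tsm_product=tsm_product)
    return expanded.data[:, 0, 0]


def expand_library(lib: SpectralLibrary, tsm_product: bool = False) -> SpectralLibrary:
    """Lift a 4-band library to the 8-band space; a no-op for 8-band libraries.

    Target samples are averaged in the raw band space *before* expansion:
    the ratio-based indices (TSM in particular) are ill-conditioned on
    individual noisy samples, while the mean spectrum is stable. Background
    endmembers (already class means) are expanded individually.
    """
    if len(lib.band_roles) == 8:
        return lib
    roles = raster_io.RAW_ROLES + band_expansion.INDEX_ROLES
    entries = [("target_mean", expand_spectrum(lib.target_mean, tsm_product), "target")]
    entries += [(n, expand_spectrum(s, tsm_product), "background")
                for n, s, r in lib.entries if r == "background"]
    return SpectralLibrary(entries, roles)


@dataclass
class PipelineResult:
    mask: BinaryMask
    scores_raw: DetectionMap
    scores_rescaled: DetectionMap
    scores_smoothed: DetectionMap | None
    otsu: OtsuResult
    whitening: WhiteningModel | None
    projector: Projector | None
    metrics: ConfusionCounts | None


def run_on_arrays(
    cube: MultispectralCube,
    library: SpectralLibrary,
    truth: BinaryMask | None = None,
    detector: str = "omf",
    use_wls: bool = True,
    expand: bool = True,
    epsilon: float = DEFAULT_EPSILON,
    project_target: bool = False,
    tsm_product: bool = False,
    wls_params=None,
    otsu_levels: int = 256,
    pa_convention: str = "ppv",
) -> PipelineResult:
    """Run the extraction pipeline on in-memory objects.

    ``detector`` is "omf" (whitened orthogonal matched filter) or "mf"
    (classic matched filter baseline). ``use_wls`` toggles the smoothing
    stage. The whole chain is deterministic.
    """
    from .wls import wls_filter  # local import keeps module load light

    if detector not in ("omf", "mf"):
        raise ValueError(f"unknown detector {detector!r}")
    if expand and cube.n_bands == 4:
        work = expand_bands(cube, tsm_product=tsm_product)
        lib = expand_library(library, tsm_product=tsm_product)
    else:
        work, lib = cube, library
    if len(lib.band_roles) != work.n_bands:
        raise ValueError("library band count does not match the (expanded) cube")

    X, shape = flatten(work)
    valid_flat = ~work.nodata_mask.ravel()
    if valid_flat.sum() < 2:
        raise ValueError("fewer than 2 valid pixels")

    whitening_model = projector = None
    if detector == "omf":
        whitening_model = fit_whitening(X[:, valid_flat], epsilon=epsilon)
        U = lib.background_matrix
        projector, d_white = whitened_projector(
            whitening_model, lib.target_mean, U if U.shape[1] else None
        )
        dmap_flat = score_omf(whitening_model, d_white, projector, X,
                              project_target=project_target)
    else:
        model = fit_classic_mf(X[:, valid_flat], lib.spectra("target"), epsilon=epsilon)
        dmap_flat = score_classic_mf(model, X)

    scores_raw = DetectionMap(
        unflatten(dmap_flat.scores, shape), dmap_flat.kind,
        ~work.nodata_mask, geo_meta=dict(work.geo_meta),
    )
    scores_rescaled = rescale_scores(scores_raw)
    scores_smoothed = wls_filter(scores_rescaled, wls_params) if use_wls else None
    final = scores_smoothed if use_wls else scores_rescaled

    otsu_result = otsu_threshold(final, n_levels=otsu_levels)
    mask = apply_threshold(final, otsu_result)

    cm = None
    if truth is not None:
        cm = confusion(mask, truth, valid=~work.nodata_mask, pa_convention=pa_convention)
    return PipelineResult(mask, scores_raw, scores_rescaled, scores_smoothed,
                          otsu_result, whitening_model, projector, cm)
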