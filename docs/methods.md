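# Methods

This note records the models, parameter choices and numerical conventions
behind `omfwls`, and what the synthetic-scene experiments do and do not show
about real imagery.

## Signal model

A pixel spectrum x (length L after band expansion) is modelled as a linear
mixture x = d·α_d + U·α_U + n of one target spectrum d, K−1 background
endmembers (columns of U) and noise. Abundances, when given, are
non-negative and sum to one; they are bookkeeping only — the detectors never
estimate them.

## Band expansion

NDVI, EVI, NDWI and TSM are stacked onto the four raw bands. Two
conventions deserve note:

* **EVI uses the green band** in its soil/aerosol term rather than the
  canonical blue band. This variant is implemented as such deliberately;
  users wanting canonical EVI should not rely on this band as a physical
  EVI product.
* **TSM's third term is a green/blue ratio**, 5.31·(B2/B1). A
  `tsm_product=True` switch computes the literal product 5.31·B2·B1
  instead. The ratio reading follows the flattened-fraction typography of
  the other indices. The ratio is ill-conditioned when blue reflectance
  approaches zero; pixels with B1 = 0 are flagged invalid, and spectra fed
  to the detector are averaged *before* expansion (see below) so the prior
  never inherits a near-zero denominator.

Division-by-zero pixels are set to 0 and merged into the nodata mask, never
propagated as NaN; this keeps all downstream statistics finite. Index
magnitudes depend on whether the input is reflectance or sensor DN; the
package accepts either and makes no attempt to harmonize scales beyond the
per-band min-max normalization of the whitening stage.

## Whitening

Per-band min-max normalization to [0, 1] over valid pixels, mean centering,
covariance C = (1/n)XXᵀ (the 1/n convention; the difference from 1/(n−1) is
far below the regularization floor), symmetric eigendecomposition, and
per-component scaling by 1/√(λᵢ + ε) with ε = 1e−5 by default. ε bounds the
amplification of near-null directions (a constant band whitens to ~0 instead
of exploding). Eigenvalues are sorted descending and each eigenvector's sign
is fixed so its largest-magnitude component is positive, making the basis
deterministic across platforms. All components are kept: the detector
operates at full rank, and rank reduction is left to the regularizer rather
than truncation. The fitted model is a single affine map applied identically
to image pixels and library spectra, and serializes to JSON.

## Detector

In whitened coordinates the background covariance is approximately the
identity, so the constrained minimum-variance filter reduces to the
normalized whitened target direction: w = d_white/‖d_white‖, score
y(s) = wᵀ x̄ₛ. This unprojected form is the package default.

The orthogonal-subspace variant (`project_target=True`) first projects
d_white onto the orthogonal complement of the whitened background
endmembers, w ∝ P_U⊥ d_white. This actively annihilates the supplied
background directions, but it is safe only when those endmembers are well
separated from the target in whitened space: with a handful of endmembers
spanning most of the class-structure subspace (e.g. water plus another
vegetation class against a vegetation target), the projection removes
nearly all target signal, and the residual direction is dominated by
estimation noise. The degenerate case ‖P_U⊥ d_white‖ ≈ 0 raises a warning
at projector construction and an error at scoring. This trade-off is why
the projection is opt-in rather than default.

The target prior is the mean of the library's target samples taken in the
raw 4-band space and then lifted through the index formulas. Averaging
before expansion matters: the ratio indices are unstable on individual
noisy samples (a single sample with near-zero blue produces an unbounded
TSM), while the mean spectrum is well-behaved.

The classic matched filter baseline estimates μ₀ and Σ from all valid
pixels (or a supplied background mask), takes μ₁ as the mean target
spectrum, and uses w = Σ⁻¹(μ₁−μ₀)/((μ₁−μ₀)ᵀΣ⁻¹(μ₁−μ₀)), so score(μ₀) = 0
and score(μ₁) = 1 by construction. Σ is ridge-regularized by ε·I when its
condition number exceeds 1e10, reusing the whitening ε as the single
conditioning knob.

## WLS smoothing

Scores are min-max rescaled to [0, 1] (a constant map rescales to 0.5 with
a warning) and smoothed by minimizing
(u−y)ᵀ(u−y) + λ(uᵀDxᵀAxDxu + uᵀDyᵀAyDyu),
solved as the sparse SPD system (I + λL)u = y via a direct sparse
factorization; the relative residual must be below 1e−8 or the filter
raises. Forward differences use replicate (Neumann) boundaries — border
difference rows are zero — so L annihilates constants and a flat image is a
fixed point for any λ.

The diagonal weights are the standard edge-preserving choice computed on
the score map itself: a = (|∇y|^α + ε_w)⁻¹. Defaults λ = 1.0 (smoothing
strength, dimensionless against unit-range scores), α = 1.2 (gradient
sensitivity), ε_w = 1e−4 (weight ceiling 1/ε_w in flat regions). On a unit
step with σ = 0.05 noise these defaults retain ~87% of the step while
cutting flat-region noise by ~70%. Nodata pixels are filled with the
valid-pixel mean for the solve only; they stay excluded from thresholding
and evaluation.

## Otsu thresholding

Valid scores are quantized to 256 levels (configurable) over their range;
thresholds 0 < T < L−1 are scanned exhaustively for the maximum
between-class variance, computed in both the decomposed form
p₁(m₁−G)² + p₂(m₂−G)² and the equivalent product form p₁p₂(m₁−m₂)² (the
two agree to rounding error and are cross-checked in tests). Ties break to
the smallest T. The threshold maps back to score units at the boundary
between levels T and T+1, and the high-score class is the target.

## Accuracy metrics

OA, AA, PA and Cohen's κ from the 2×2 confusion matrix over valid pixels.
PA here is TP/(TP+FP) — positive predictive value — which differs from the
usual remote-sensing definition of producer's accuracy, TP/(TP+FN);
`pa_convention="standard"` selects the usual form. Metrics with an empty
denominator are reported as NaN with a flag, never silently zeroed.

## Synthetic scenes

The generator emulates a coastal scene: class patches from thresholded
smoothed Gaussian fields (patch_scale = 8 px smoothing, giving irregular
boundaries of the kind the WLS stage must preserve), default class
reflectances mangrove (0.04, 0.06, 0.04, 0.50), water (0.06, 0.05, 0.03,
0.01), soil (0.10, 0.12, 0.14, 0.20), other vegetation (0.05, 0.07, 0.06,
0.35), target fraction 0.3, i.i.d. per-band Gaussian noise (an optional
mixing mode induces inter-band noise correlation to exercise whitening),
and canopy gaps: a chosen fraction of target pixels mixed 60% toward the
water spectrum while remaining target in the truth mask. The library holds
10 noisy target-pixel samples and the water and other-vegetation class
means as background endmembers. Everything derives from one integer seed.

What the scenes do not emulate: radiative transfer, spatially correlated
noise, mixed boundary pixels, tidal/seasonal spectral dynamics, or sensor
artifacts. Passing tests on these scenes demonstrate the algebraic and
statistical correctness of the chain and the qualitative benefit of WLS
smoothing under noise and canopy gaps — not absolute accuracy on real
satellite scenes.

## Problem sizes and determinism

The test suite runs scenes up to 256×256 (65,536-unknown sparse solves) and
ten-seed medians for the noisy comparisons; these sizes give stable medians
while keeping the suite fast. The pipeline itself contains no randomness:
given a scene, a library and a configuration it is bit-reproducible, and
the scene generator is bit-reproducible given its seed.

## Known limitations

* Endmember extraction is out of scope; background endmembers come from the
  spectral library (a heuristic eigenvector-based fallback exists for
  whitened backgrounds, labelled as such).
* The dense L×L projector is used; no sparsification is attempted.
* Min-max rescaling of scores is outlier-sensitive: a few extreme-score
  pixels (e.g. TSM blow-ups on noisy low-blue pixels) compress the useful
  score range before quantization. The 256-level Otsu scan still resolves
  the main modes in practice.
* Geo metadata is carried as an opaque dict in the raster container and
  file sidecars; the package does not interpret CRS or transforms.
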