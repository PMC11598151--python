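# omfwls

Spectral target extraction from 4-band multispectral imagery by whitened
orthogonal matched filtering with edge-preserving weighted-least-squares
smoothing (OMF-WLS), plus automatic Otsu binarization and accuracy
assessment. The package targets the kind of problem faced in coastal
vegetation mapping — picking mangrove canopy out of water, bare soil and
other vegetation in blue/green/red/NIR scenes — but every stage is generic:
it needs only a raster, a handful of sampled target spectra, and optionally
background endmember spectra and a ground-truth mask.

## Method

Given a scene with bands B1..B4 (blue, green, red, NIR):

1. **Band expansion.** Four derived indices are stacked onto the raw bands
   to sharpen target/background separability, giving an 8-band cube:
   NDVI = (B4−B3)/(B4+B3), EVI = 2.5(B4−B3)/(B4+6B3−7.5B2+1),
   NDWI = (B2−B4)/(B2+B4), TSM = 0.028B1+0.019B2−5.31(B2/B1)+0.537.
2. **Regularized PCA whitening.** Pixels are min-max normalized per band,
   mean-centered, and the covariance C = (1/n)XXᵀ is eigendecomposed,
   C = UΛUᵀ. Each rotated component is scaled by 1/√(λᵢ+ε) (ε ≈ 1e−5), so
   the background covariance becomes ~identity and a plain dot product acts
   as a matched filter.
3. **Whitened matched filtering (OMF).** The target prior d is the average
   of sampled target spectra, lifted to the 8-band space and whitened. The
   detector is w = d_white/‖d_white‖ and the score of pixel s is
   y(s) = wᵀx̄ₛ with x̄ₛ the whitened pixel. An orthogonal subspace
   projection P = I − U(UᵀU)⁻¹Uᵀ built from whitened background endmembers
   can additionally be applied to d_white (`project_target=True`) to
   annihilate known background directions.
4. **WLS smoothing.** The min-max-rescaled score map y is smoothed by
   solving (I + λL)u = y, L = DxᵀAxDx + DyᵀAyDy, with gradient-adaptive
   weights a = (|∇y|^α + ε_w)⁻¹ — strong averaging in flat regions, almost
   none across edges (λ = 1, α = 1.2, ε_w = 1e−4 by default).
5. **Otsu thresholding.** The smoothed map is quantized to 256 levels and
   the threshold maximizing the between-class variance
   σ²(T) = p₁p₂(m₁−m₂)² is applied; the high-score class is the target.
6. **Accuracy.** Against a truth mask, the 2×2 confusion matrix yields
   OA, AA, PA = TP/(TP+FP) and Cohen's κ.

A classic matched filter (w ∝ Σ⁻¹(μ₁−μ₀), unit gain on the target contrast)
is included as a baseline, and a seeded synthetic-scene generator produces
4-band scenes with spatially coherent classes, per-band Gaussian noise,
canopy gaps and known truth, so the whole chain is testable without
satellite data.

## Worked example

```bash
python examples/extract_targets.py
```

```
scene: 256x256, noise sigma 0.05, 30.0% target pixels
otsu threshold: 0.5708 (level 131 of 256)
OA    = 0.74515   fraction of pixels labelled correctly
AA    = 0.81481   mean of target recall and background recall
PA    = 0.54118   fraction of detected pixels that are real targets
Kappa = 0.50923   agreement beyond chance (1 = perfect)
```

The scene has substantial per-band noise and 20% of target pixels degraded
toward the water spectrum (canopy gaps), so this is a deliberately hard
case; on a noise-free scene the pipeline recovers the truth mask exactly
(κ = 1). The other scripts in `examples/` demonstrate individual stages:
band expansion (`band_indices.py`), whitening (`whitening_demo.py`),
edge-preserving smoothing (`wls_smoothing.py`) and a detector comparison
across noise levels (`detector_comparison.py`).

The same pipeline is available from the shell:

```bash
omfwls simulate --out scene.tif --truth truth.tif --library lib.csv --seed 7
omfwls run --input scene.tif --library lib.csv --out mask.tif --truth truth.tif
omfwls evaluate mask.tif truth.tif
```

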