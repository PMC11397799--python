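# Methods

## The problem

Top-view multispectral imaging is a fast, non-destructive way to track the
nutrient status of potted plants. A camera rig illuminates the plant with
single-wavelength LEDs — red, green, blue, near-infrared (NIR) — one at a
time and records one grayscale image per wavelength, plus a chlorophyll
fluorescence image (blue excitation, long-pass filter > 665 nm, so only
chlorophyll-containing tissue appears bright). From such a stack the
pipeline derives, per plant and timepoint:

* a **plant mask** of photosynthetically active pixels, from the
  fluorescence channel;
* **per-pixel spectral indices** over the mask — NDVI
  `(NIR − red)/(NIR + red)` and an anthocyanin content index (ACI);
* **projected canopy size**: the count of mask pixels, a 2D proxy for
  biomass;
* scalar summaries (index mean/SD, fluorescence mean) that feed a
  **quadratic treatment-response regression** across an experiment.

A hardware quirk drives one extra stage: the NIR optical path focuses
differently from the visible channels, so the NIR image arrives shifted
and mildly warped relative to the others and must be registered onto the
red channel before any band math.

## Pipeline order and conventions

Registration runs first, then masking, then indices, so the mask and all
index maps share one frame. Rasters are addressed `(row, col)`, 0-based,
top-left origin. Intensities are normalized to [0, 1] floats at load by
dividing by `2^bit_depth − 1`; all downstream math uses normalized digital
numbers, which makes band ratios bit-depth invariant. No radiometric
calibration to reflectance is attempted (the acquisition protocol has no
calibration target); index values are therefore comparable within one
system but not across instruments — a known limitation.

## Registration

Default model is **pure translation** estimated by phase correlation
(`skimage.registration.phase_cross_correlation`), refined to `1/upsample`
pixel (default 1/20). Sign convention, fixed and tested: the reported
`(dy, dx)` is the displacement of the moving channel's content relative to
the reference — i.e. the shift the hardware injected — and the correction
resamples the moving channel back by `(−dy, −dx)` with bilinear
interpolation. Pixels whose source coordinate falls outside the moving
frame are zeroed and flagged invalid so they never enter index statistics.

The opt-in **affine model** (for the "warp" part of the misalignment)
first estimates per-tile translations on a grid (default 4×4), fits a 2×3
affine to the tile-center displacement field by least squares, then
polishes the fit photometrically: Gauss–Newton on the z-scored sum of
squared differences between reference and warped moving image, with a
symmetric (ESM-style) gradient — the mean of the reference gradient and
the warped moving gradient — and cubic interpolation. Both channels are
standardized first because canopy/background contrast differs strongly
between bands. On well-textured scenes the polish sharpens the linear
entries to ~1e-5 and the translation entries to a few thousandths of a
pixel; accuracy is texture-limited, so a single central blob (texture only
at its rim) registers far worse than a scene with material in every tile.

Confidence is the Pearson correlation between the reference and the
corrected moving channel over the in-frame overlap, clipped to [0, 1].
Below 0.1 the estimate is considered unreliable and batch processing falls
back to the identity transform with a logged warning instead of failing.

## Segmentation

Foreground is the set of fluorescence pixels **strictly above** a
threshold chosen by Otsu's method by default (parameter-free; the actual
threshold is always recorded so any run can be reproduced with
`method="fixed"`). Cleanup: morphological opening then closing (disk
radii, default 0 = off), removal of 8-connected components smaller than
`min_component_px` (default 50 px — drops noise specks while keeping the
separate blobs a trailing plant legitimately produces), and an optional
largest-component-only mode (off by default for the same reason).
Components use 8-connectivity throughout. Otsu on a constant image raises
a degenerate-histogram error rather than guessing.

## Indices and statistics

Index maps carry a `valid` raster: on-mask ∧ nonzero denominator ∧
in-frame after registration. Invalid pixels hold NaN but the `valid`
raster is authoritative; they are excluded from means, SDs, histograms and
false-color rendering (rendered black). Statistics are the mean and
**population** SD (ddof = 0) over valid pixels; an empty valid set returns
an explicitly undefined-flagged result rather than NaN.

ACI has no standardized formula at these wavelengths; the default here is
the per-pixel red/green ratio (the system lacks the red-edge bands of the
usual anthocyanin indices). The formula id is recorded on every map and in
outputs, and green/nir or red/nir can be selected instead.

False-color rendering maps valid pixels through a fixed colormap
(viridis; the id is part of the output metadata) over a fixed default
display range (NDVI: [−0.2, 0.9]) so images are visually comparable across
timepoints; rendering is a pure function of (map, vmin, vmax, colormap).
Histograms default to 50 bins over the index's theoretical support, with
out-of-range values clipped into the end bins so counts always sum to the
number of valid pixels.

## Treatment-response regression

For each cultivar and metric, ordinary least squares of the metric on
`(1, x, x²)` where `x` is the treatment level (e.g. fertilizer g/pot or
solution pH). Reported: coefficients, `R² = 1 − SSE/SST`, and the overall
F-test p-value, `F = ((SST − SSE)/2)/(SSE/(n − 3))` on `(2, n − 3)` df —
the probability of no treatment effect. Per-coefficient t-test p-values
are supplementary columns. The quadratic degree is fixed: it captures both
a saturating monotone response and an interior optimum while keeping one
p-value per (cultivar, metric). Fits require ≥ 4 observations and ≥ 3
distinct levels; they never pool across cultivars. No multiple-testing
correction by default (Benjamini–Hochberg available via a flag). Group
summaries report mean ± SEM (sample SD/√n; undefined at n = 1) per level.

## Synthetic scenes and what they do (not) show

No public image archive exists for this instrument class, so verification
uses generated scenes with analytic ground truth. A scene is a union of
ellipses (the canopy) on a dark background; each channel gets a flat
canopy and background intensity, Gaussian sensor noise is added and
clipped to [0, 1], the NIR channel is resampled by the injected shift or
affine (bilinear, background fill), and everything is quantized to 8 or 16
bits — quantization after misalignment, so the injected transform is
exactly what registration must recover. Ground truth carries the
pre-misalignment mask, its pixel count, the band-implied index values, and
the injected transform. Generation is fully deterministic in the seed,
with channels drawn in a fixed order so dict ordering cannot perturb the
RNG stream.

Default conditions: 8-bit depth, sensor noise SD 0.01 (about 2.5 gray
levels), canopy bands red 0.15 / green 0.35 / blue 0.10 / NIR 0.80 /
fluorescence 0.70 against a dark substrate background — implying NDVI
≈ 0.68, the regime of a healthy well-fertilized canopy.

The synthetic experiment emulates a fertilizer dose-response trial: 6
levels (0, 0.5, 1, 2, 4, 8 g/pot) × 8 replicates, one plant per scene,
every scene carrying the same injected NIR shift (3, −5). The response
functions are quadratics in the level — target NDVI
`0.40 + 0.06x − 0.0045x²` (rising steeply then saturating, ≈ 0.40 → 0.59
across the range) and canopy radius `18 + 3x − 0.15x²` px — with
replicate-level Gaussian jitter (SD 0.02 on target NDVI, 1.5 px on radius)
giving recovery tests a controlled noise floor on top of pixel noise. The
NIR and red band values are solved from the target NDVI holding
NIR + red = 0.9.

Ellipse canopies with flat bands are deliberately unrealistic: analytic
ground truth beats texture realism for code verification. Passing tests
therefore demonstrate that the *code* computes what it claims on known
inputs — they do not demonstrate segmentation robustness to leaf-level
texture, specular highlights, overlapping neighbor plants, or illumination
gradients, none of which the generator emulates.

## Verification problem sizes

The verification suite and `scripts/acceptance.py` use: 128×128 disk
scenes for mask/NDVI/canopy checks; 100 seeded trials for noisy integer
shift recovery (±10 px, noise SD 0.02); one 320×320 16-bit scene with 120
scattered blobs for affine recovery (texture in every tile, which the
affine model requires); 1000 null replicates and 500 effect replicates
(n = 48 each) for regression calibration; and 100 seeded end-to-end
experiments (48 scenes of 96×96 each) for power plus 100 for null
uniformity. A full acceptance run takes about a minute on one core.

## Numerical choices and edge cases

* Thresholding uses strict inequality; ties at the threshold are
  background.
* Quantization rounds to nearest (`rint`), so a round-trip through image
  files is exact for quantized data and within one step for floats.
* `estimate_shift` on identical arrays returns exactly (0, 0); an
  identity transform applied to a stack is a bitwise no-op.
* Zero-variance rasters are rejected for registration (degenerate-image
  error) rather than returning an arbitrary peak.
* A perfect quadratic fit (SSE ≈ 0) reports p at the floating-point floor
  rather than statsmodels' NaN.
* Empty masks are legal everywhere and propagate as explicit undefined
  values (empty CSV fields), never as silent NaN.
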