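# canopyspec

Multispectral top-view plant phenotyping: chlorophyll-fluorescence-driven
segmentation, infrared channel registration, per-pixel spectral indices,
projected canopy size, and quadratic treatment-response regression.

## What it does

Low-cost plant imaging rigs capture one grayscale image per LED wavelength
— red, green, blue, near-infrared (NIR) — plus a chlorophyll fluorescence
image in which only photosynthetically active tissue appears bright.
`canopyspec` turns such a stack into quantitative plant-status metrics:

1. **Registration** — the NIR optical path is misaligned relative to the
   visible channels; the shift (or mild affine warp) is estimated against
   the red channel by phase correlation and corrected before any band
   math.
2. **Segmentation** — the fluorescence image is thresholded (Otsu by
   default) into a plant mask, so background never contaminates index
   statistics.
3. **Indices** — per masked pixel, NDVI = (NIR − red)/(NIR + red) and an
   anthocyanin content index (red/green by default). Means and SDs are
   taken over valid pixels only.
4. **Canopy size** — the mask pixel count, a 2D proxy for biomass.
5. **Regression** — for each cultivar and metric, ordinary least squares
   of the metric on treatment level and its square, summarized by R² and
   the overall F-test p-value (mean ± SEM per treatment group alongside).

Because no public image archive exists for this instrument class, the
package ships a synthetic-scene generator with full ground truth (mask
geometry, band values, injected NIR misalignment, dose-response structure)
against which every stage is verified. See `docs/methods.md` for the
model details and limitations.

## Worked example

Generate a synthetic scene, analyze it, and fit a dose response:

```sh
canopyspec simulate --out demo --seed 5
canopyspec analyze --manifest demo/manifest.csv \
    --plant synthetic --timepoint t0 --out demo_results
```

which prints

```
scene written to demo (canopy 5025 px)
synthetic@t0: canopy 5025 px, NDVI 0.6843 ± 0.0181
```

The simulated plant is a disk of 5025 px with canopy band values NIR 0.80
and red 0.15 (true NDVI (0.80 − 0.15)/(0.80 + 0.15) ≈ 0.684); the
pipeline recovers the canopy size exactly and the NDVI mean to the third
decimal despite 8-bit quantization and sensor noise, with the small SD
coming from that noise. `demo_results/` also contains the mask PNG, the
NDVI/ACI false-color renderings, and the index histograms.

For a whole experiment (many plants, a treatment column in the manifest):

```sh
canopyspec batch --manifest experiment/manifest.csv --out results
canopyspec regress --summaries results/batch_summary.csv \
    --metric ndvi_mean --out fits.csv
```

`regress` prints one line per cultivar, e.g.

```
all/ndvi_mean: y = 0.4024 + 0.05609x + -0.003997x², R² = 0.928, p = 1.94e-26 (n=48)
```

— here recovering the quadratic NDVI dose response that the synthetic
experiment was built with (true coefficients 0.40, 0.06, −0.0045).

In Python, the same pipeline is three calls:

```python
from canopyspec import generate_scene, SyntheticSceneSpec, analyze_stack

stack, truth = generate_scene(SyntheticSceneSpec(nir_shift=(3, -5), seed=1))
analysis = analyze_stack(stack)          # register -> mask -> NDVI/ACI -> summary
print(analysis.summary.canopy_size_px, analysis.summary.ndvi_mean)
```

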