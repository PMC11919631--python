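# voidspot

Detection, quantification and summary of mouse urine spots on absorbent
filter paper — the void spot assay (VSA).

In a VSA, a mouse is housed for a few hours on filter paper; urine
fluoresces under 365 nm UV light and the size and number of spots report
bladder voiding behaviour. Quantifying those photographs by software is
hard in practice: UV illuminators leave steep background gradients, the
urine/paper contrast varies with diuresis, paper brand and lamp, some
spots appear *darker* than the paper ("inverse" coloration), and papers
carry non-void artifacts (writing, glue bleed-through, chewed edges).
`voidspot` provides a complete pipeline for this problem that can be
exercised and validated end to end on synthetic scenes with exact ground
truth.

## What is in the package

- **`raster_io`** — 8-bit grayscale TIFF/PNG images, per-spot areas CSVs
  (`<label>_areas.csv`, header `id,area`), overlay PNG rendering.
- **`annotations`** — ImageJ/Fiji `.roi` binary codec (polygon, freehand,
  oval, rectangle) and `RoiSet.zip` archives; rasterization of outlines to
  instance masks (pixel-center even-odd fill plus traced boundary).
- **`synth_scenes`** — synthetic filter-paper scenes: illumination
  gradients, bright/faint/inverse spots, writing/glue/tear artifacts,
  rectangular and circular filters, and a pipetted volume ladder
  (1–150 μL in duplicate) — all with pixel-exact truth masks.
- **`training_data`** — quadrant tiling of annotated full-frame images and
  seeded training-set selection.
- **`detectors`** — two interchangeable detectors behind one contract: a
  deterministic median-background thresholding baseline, and a trainable
  gradient-boosted pixel classifier over a multi-scale filter bank with
  connected-component instancing.
- **`tiled_inference`** — deployment of any detector on large rasters by
  grid tiling with overlap, IoU-based fusion and seam-fragment union.
- **`calibration`** — the area:volume standard curve. On a given paper the
  wetted area *A* (px²) grows linearly with deposited volume *V* (μL), so
  a single OLS fit `V = βA + α` calibrates the conversion.
- **`void_summary`** — per-filter aggregation: paper/background
  segregation, volume conversion, binning into **primary voids**
  (> 20 μL) and **micro voids** (1–20 μL; sub-1 μL spots are excluded as
  likely claw marks or fur contamination), and a folder-level
  `VoidDataSummary.csv`.
- **`evaluation`** — per-image count regression (OLS of predicted count on
  ground-truth count) and per-spot greedy IoU mask matching with
  precision/recall.

## Worked example

Calibrate from a pipetted ladder, detect, and summarize — entirely from
the shell:

```sh
voidspot ladder --seed 2 --out lad                 # volume ladder scene
# build (area, volume) pairs from the ladder truth, then:
voidspot calibrate pairs.csv --out curve.txt
# -> slope=0.0100011 intercept=0.0151378 r_squared=1.0000 n=16

voidspot synth --n-images 3 --seed 42 --n-spots 6 --radius-max 25 --out scenes
voidspot detect scenes/*.tif --rows 2 --cols 2 --out detections
voidspot summarize detections --curve curve.txt
```

`detections/VoidDataSummary.csv` then reads:

```
Image,Total_Volume (μl),Total_Spot_No.,Primary_Voids,Primary_Voids_Mean_Volume (μl),Micro_Voids
scene_000042_areas.csv,47.8,6,0,0.0,6
scene_000043_areas.csv,30.4,6,0,0.0,6
scene_000044_areas.csv,58.8,6,0,0.0,6
```

The ladder was generated at 100 px² per μL, and the fitted slope is
0.0100 μL/px² — the calibration recovers the generating constant. Each
synthetic scene contained six true spots and the detector reports six,
with every spot in the 1–20 μL micro-void bin at these spot sizes; the
totals are the summed calibrated volumes per filter, printed to one
decimal.

The same chain runs on real photographs: convert them to 8-bit grayscale
TIFF, annotate a subset in Fiji (`RoiSet.zip` per image), train with
`voidspot train`, and pass `--model` to `voidspot detect`.

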