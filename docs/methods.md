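# Methods

## The measurement problem

A void spot assay photograph is an 8-bit grayscale raster of filter paper
on which urine spots must be found, delineated as pixel masks, and
converted to volumes. The physical model is simple: on a given paper the
wetted area grows linearly with deposited volume, so a per-setup standard
curve `V = β·A + α` (β in μL/px², fitted by ordinary least squares of
volume on area, the deployment direction) turns instance segmentation
into volumetry. Everything difficult lives in the segmentation: uneven
illumination, variable contrast including inverse (darker-than-paper)
spots, and non-void artifacts.

## Synthetic scenes as the test bed

Because archived photographs are not part of the package, every stage is
validated on generated scenes with exact truth. A scene is

    background  =  base + gradient + Gaussian noise, clipped to [0, 255]
    spot        =  boundary-perturbed ellipse, opacity blurred at the edge
    truth mask  =  pixels with opacity ≥ 0.5, taken before noise

with artifacts (pencil strokes, glue blobs, jagged tears) recorded in the
truth inventory but never counted as spots. Defaults describe a plausible
bench setup at desk scale: 512×512 frames, paper at 120/255 with a ±40
planar gradient, noise SD 3, spot radii 5–40 px at 100 px² per μL (about
0.8–50 μL, spanning sub-microliter marks to primary voids), contrast
+40–80, edge blur 1 px. One `numpy` Generator seeded per scene drives all
draws, so output is byte-identical per seed. The pipetted ladder uses the
standard duplicate series 1, 2, 5, 10, 25, 50, 100, 150 μL; disc radii
are bisected so each rasterized area matches `volume × px_per_ul` within
2 %, and ladder truth volumes are the pipetted values (the generating
constant is what calibration must recover).

What the generator does **not** emulate: paper texture, fluid-spread
physics, overlapping-spot morphology beyond an optional controlled-IoU
pair mode, fur/claw streaks beyond line artifacts, or chewed-and-repaired
paper. Passing tests therefore demonstrate correctness of the pipeline
mechanics and detector behaviour across the documented contrast/gradient
regimes, not photographic realism.

## Baseline detector

The baseline estimates background with a sliding-window median
(`bg_window_px = 61`, which tracks smooth gradients exactly on a ramp
since the median of a linear function over a symmetric window is its
center value), thresholds the residual at `k·σ` (k = 3) with a floor of
3.5 counts — 8-bit quantization plus window reflection at the frame
border leaves up to ~3 counts of wobble even on a noise-free ramp — and
instances 8-connected components after hole filling, discarding those
below `min_area_px = 9`. With `detect_dark` it also thresholds the
negative residual, which captures inverse spots. The window must exceed
the largest spot diameter or the median is contaminated from inside the
spot; on clean hard-edged scenes the baseline reproduces truth masks
bit-exactly, which makes it the oracle for the tiling and evaluation
stages.

## Trainable detector

The learned detector is a gradient-boosted pixel classifier
(scikit-learn `HistGradientBoostingClassifier`) over a 10-channel
per-pixel filter bank: raw intensity, Gaussian smoothings (σ = 1, 2, 4),
Sobel gradient magnitude at the same scales, and background-subtracted
residuals (intensity minus σ = 16 and σ = 32 Gaussians) that carry the
urine/paper contrast independent of illumination. Training samples are
quadrant tiles with instance masks; pixels are subsampled (≤ 12 000 per
tile, foreground-enriched, seeded). One nominal epoch corresponds to 10
boosting rounds at the given learning rate (default 0.1); the default 8
epochs train in well under a minute on one CPU for 40 tiles of 256×256.
Deployment thresholds the per-pixel void probability at 0.5, fills
holes, instances 8-connected components, scores each instance by its
mean probability, and filters by `min_area_px = 9` and
`score_threshold = 0.5` — 9 px is far below any 1 μL spot at realistic
resolution, so the sensitivity floor of about 1 μL is set by the
training label distribution, not the thresholds. There is no pretrained
initialization for this family; metadata records `pretrained: false`.
Artifact-bearing tiles in the training set teach the classifier to label
writing and glue as background.

## Tiled deployment and merging

Large frames are cut into a rows×cols grid (boundaries at
`round(i·N/parts)`), each tile extended by `overlap_px` into its
neighbours (default 64 for the learned detector, 0 for the baseline,
whose window already provides context). Per-tile detections are
translated to frame coordinates and fused by union–find: pairs from
different tiles merge when mask IoU ≥ 0.3 (low, because the same spot
may be partially cropped in one tile) or when fragments touch across a
seam under 8-connectivity. Contested pixels go to the higher-scoring
group, ties to the earlier raster position, so the merged set keeps the
disjointness invariant. Grid choice does not affect results when spots
stay clear of the seams by at least half the background window;
seam-adjacent spots can shift by a few boundary pixels because each tile
pads its border by reflection.

## Summary stage

Per filter: areas → volumes via the curve; bins are primary (> 20 μL)
and micro (1–20 μL inclusive on both ends — exactly 20 μL is micro,
exactly 1 μL is micro); spots under 1 μL are excluded from every count
and total and logged. Totals are summed then rounded to one decimal
(sum-then-round matches the reference arithmetic at printed precision);
the primary mean is reported as 0 when there are no primary voids. The
folder stage writes `VoidDataSummary.csv` with the verbatim header
`Image,Total_Volume (μl),Total_Spot_No.,Primary_Voids,Primary_Voids_Mean_Volume (μl),Micro_Voids`,
rows ordered by file name, overwriting deterministically. Paper/
background segregation uses Otsu thresholding with a bimodality guard
(dark class ≥ 10 % of the frame and mean below 0.45× the bright mean):
when a dark surround is present the paper is the largest bright
connected region with holes filled, and detections whose centroids fall
off-paper are dropped; otherwise the whole frame is paper. The areas CSV
format carries no pixel coordinates, so off-paper filtering applies in
the detection path, not to pre-exported tables.

## Evaluation

Count regression fits predicted count on truth count so slopes are read
as "predictions per true spot"; it refuses degenerate inputs (all truth
counts equal). Mask matching is greedy in descending IoU with a default
threshold of 0.5 — deterministic and standard for detection evaluation;
at the spot densities seen here optimal assignment would not change the
result. Empty-set conventions: no predictions → precision 1, recall 0
(and vice versa), logged.

## Numerical and design choices

- Bit-depth rescaling is linear over the source dtype range, never
  per-image min–max, so blank frames stay blank.
- ROI rasterization: vertices live on the pixel-corner grid; a pixel is
  in a polygon if its center is inside (even-odd rule) or on the traced
  Bresenham outline. Rectangle ROIs use right/bottom-exclusive bounding
  boxes (a 10×10 rectangle has area 100); ovals are analytic
  center-inside ellipses.
- ROI names round-trip through the second binary header (UTF-16BE), and
  zip members are sorted by name for determinism.
- Quadrant splitting floors the first half (odd dimensions put the extra
  pixel right/bottom); training-label fragments under 4 px after
  clipping are dropped as unlearnable slivers.
- Curve fitting refuses non-positive volumes and identical areas;
  applying a curve clamps negative extrapolations to 0 μL and counts the
  clamp events on the curve object.
- Problem sizes in the test suite (256–512 px scenes, 40 training tiles,
  20 evaluation scenes, 50 oracle seeds) are the package's desk-scale
  defaults for full-pipeline validation.

## Known limitations

- Overlapping spots are not separated; the optional overlap mode exists
  to exercise the failure, not to solve it. Heavily overlapping voids
  need manual editing upstream, as in standard Fiji practice.
- The pixel classifier has no shape model, so a non-void object with
  urine-like local contrast and texture can be detected; shape-aware
  rejection is future work.
- The baseline's median window must exceed the largest spot diameter;
  very large primary voids need a larger window than the default.
- Count-regression figures on synthetic scenes characterize the pipeline
  under the generator's regimes and are not claims about any particular
  photographic dataset.
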