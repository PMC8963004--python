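# Methods

## Color-index classification

Photogrammetric densification assigns each 3D point the RGB of the imagery
it was matched in. Chromatic (intensity-normalized) coordinates
`r = R/(R+G+B)`, `g`, `b` remove overall brightness, so the normal
green-red difference index `NGRDI = (g − r)/(g + r)` depends only on hue
balance: +1 for pure green, −1 for pure red, 0 for gray. Because the
chromatic coordinates cancel any uniform channel scaling, pre-dividing the
8-bit channels by 255 is a mathematical no-op for the index; the test suite
asserts this invariance rather than assuming it.

Degenerate colors need explicit rules the index itself does not supply:
pure black (`R=G=B=0`) maps to chromatic `(0,0,0)`, and any point with
`g + r = 0` (black or pure blue) gets `NGRDI = 0` — neutral, which under a
vegetated scene's positive threshold lands in nonvegetation. Both rules are
deliberate: such points are never live foliage.

**Otsu threshold.** The NGRDI distribution over a scene with green canopy
and brown/gray soil is bimodal. The split maximizes the between-class
variance over a histogram of 256 uniform bins spanning the observed
`[min, max]` (256 mirrors 8-bit grayscale practice while adapting to the
index's real-valued domain). The returned threshold is the **upper edge of
the argmax bin**; when the optimum is a plateau — every cut through an
empty gap between the modes ties exactly — the lowest tied edge is taken,
with a 1e-9 relative guard against last-ulp noise in the cumulative sums.
Classification is strict (`NGRDI > t*` is vegetation), so threshold ties
fall conservatively to ground. All values identical is an error, not a
threshold. A warning (not an error) is logged when either class receives
under 1% of points, since Otsu on a unimodal distribution still returns a
number.

## Progressive TIN baseline

The elevation-only baseline seeds a terrain model with the lowest point of
each 10 m grid cell, discards seeds more than `spike` from the median of
their 8 neighboring seeds (bird/noise removal), triangulates (Delaunay on
the planimetric coordinates), and iteratively accepts unlabeled points
whose vertical distance to their containing facet is ≤ `bulge` above or
≤ `spike` below, re-triangulating until a pass adds nothing. A terminal
sweep accepts points within `offset` above the final surface; points
outside the seed hull are tested against the planar extension of a facet
incident to the nearest triangulated vertex. Defaults: step 10 m, bulge
0.5 m, spike 1 m, offset 0.05 m — standard settings for UAV photogrammetric
clouds over plantations.

The exact acceptance semantics of the proprietary tools implementing this
filter are not published; the variant above was chosen because every rule
is testable and it reproduces the filter's characteristic failure: any
vegetation within `bulge` of the terrain (a 0.3 m shrub layer, say) is
accepted as ground, and under heavy canopy occlusion isolated canopy points
can be captured through the extrapolated boundary facets, producing the
"islands" of inflated elevation that motivate the color-index route.
Within a pass candidates are evaluated against the pass-start surface in
ascending elevation, making the result order-independent and deterministic.

## Surface models

Rasters are north-up, 1 m cells by default. The DEM aggregates ground (or
nonvegetation) points by per-cell **minimum** — robust against residual
canopy points that survive classification. Empty cells are filled by
linear interpolation over the Delaunay triangulation of non-empty cell
centers and nearest-neighbor extrapolation beyond their hull, so a DEM has
no holes. The DSM takes the per-cell maximum over **all** points; the CHM
is `DSM − DEM` clamped at 0 (a cell whose highest point sits below the
interpolated terrain is noise, not negative canopy), and cells with no
points get 0. "Highest point per cell" interprets the 1 m assignment
literally as the raster cell rather than a 1 m disk around the cell
center; at matching resolution the two differ negligibly and the cell rule
is exact and fast.

The apex-search smoothing is a 3×3 Gaussian kernel, normalized to unit
sum, reflected at edges. The kernel width is fixed by the window; sigma
defaults to 0.5 cells because a 3×3 support materially truncates anything
wider (at sigma ≥ 1 the kernel is nearly flat and the filter stops being
meaningfully Gaussian).

## Crown individualization

Treetop search runs on the **smoothed** CHM — smoothing exists to merge
within-crown micro-maxima — while crown thresholds evaluate on the
unsmoothed CHM, whose heights are physical. A cell is an apex iff its
value is ≥ `min_height` (7 m; raising it only removes treetops, a
monotonicity the tests sweep) and is the maximum of the square window of
half-width `round(max_radius / cell)` (2 cells at 1 m resolution, a 5×5
window). Equal-valued plateau cells within one window keep only the
row-major-first cell — determinism over geometric nicety, defensible
because a plateau is one physical apex.

Crowns grow by seeded region growing in descending CHM order, swept to a
fixed point: a cell joins a crown when 4-connected to it (8-connectivity
leaks across diagonal gaps between adjacent crowns at 1 m resolution),
within `max_radius` of the apex, at least `exclusion × apex height` tall,
and unassigned; contested cells go to the planimetrically nearest apex,
ties to the taller one. The exclusion default 0.66 follows the stated
semantics of the parameter — a value of `e` excludes cells below a
fraction `e` of the tree's own height. The centroid is the unweighted mean
of member cell centers; the projected area is `cells × cell²`.

## Evaluation

Reference stems and detections are clipped to circular plots (12.7 m
radius ⇒ 506.7 m², boundary inclusive). Matching is greedy nearest-pair,
one-to-one, capped at 2.5 m (the maximum crown radius) — standard practice
for individual-tree validation; on small instances the tests verify it
attains the optimal assignment. S, P and F are computed from the counts,
with the F-score evaluated as `2TP/(2TP+FP+FN)`, the algebraically
identical form that stays exact in floating point. Precision is defined 0
with no detections; a plot without reference trees is an error. Reported
values round half-up to 2 decimals (shares of the reference total to 1).

Aggregation over plots uses **unweighted per-plot means**, which is what
reproduces the published mean statistics of the bundled 30-plot validation
table; count shares are computed against the manual inventory total
(660), since a few printed rows do not satisfy `TP + FN = manual` and the
published shares are relative to 660. The bundled CSV stores the printed
numbers verbatim, inconsistencies included; the `TP + FN = reference`
invariant is asserted only on this package's own matching output.

## Synthetic plantations

The generator emulates what matters to this pipeline and nothing more:

- terrain = plane + low-frequency sinusoid (default 0.5 m amplitude,
  40 m wavelength) — smooth at the 10 m seed-grid scale;
- ground points uniform at the stated density with 5 cm vertical
  roughness, mean color brown (NGRDI ≈ −0.13);
- crowns as cone or paraboloid surfaces of revolution over the footprint
  disk, vertical extent 0.6 × tree height, sampled uniformly in projected
  area, plus 20% interior scatter mimicking photogrammetric depth noise,
  plus the exact apex (the canopy surface photogrammetry always sees);
  mean color green (NGRDI ≈ +0.27), per-channel color noise sd 12 counts;
- canopy occlusion: a fraction (default 0.5) of ground points under crown
  footprints removed;
- optional understory: green points 0.2–0.5 m above the terrain across
  the extent.

Default density is 79 points/m² of footprint, matching the reported
densification of the motivating survey. What the simulator does **not**
model: shadows and illumination gradients, color bleeding at crown edges,
co-registration error, off-terrain artifacts (buildings, stumps), or
species mixtures — so passing tests demonstrate algorithmic correctness
and the qualitative color-vs-elevation contrast, not radiometric
robustness on real imagery.

Problem sizes in the tests and the acceptance script: a 50-tree
jittered-grid stand (6 m spacing, 15–25 m apexes, 2–2.5 m crowns) and a
24-tree understory stand, both at 25 points/m² — roughly 60–70k points
each, enough that every raster cell is multiply sampled while the whole
suite runs in seconds.

## Numerical and interface choices

- LAS 1.2 point formats 2/3 are read and written natively (fixed-size
  records); 16-bit LAS color maps to 8-bit by `/257` with half-up
  rounding, whose inverse `×257` makes color round trips exact.
  Coordinates are quantized at 1 mm. LAZ is recognized and rejected with
  a clear error. Class labels use ASPRS codes (1/2/4); because both
  ground and nonvegetation map to code 2, the plain-text format (which
  stores the label verbatim) is the lossless one for labels.
- Rasters are stored as ESRI ASCII grid — plain text, carries the full
  geotransform, readable everywhere.
- Coordinates are planimetric meters in whatever projected CRS the input
  uses; the CRS is metadata and is never transformed.
- All stochastic components take explicit seeds; identical configuration
  and seed give byte-identical outputs (scene clouds, detection CSVs).

## Known limitations

- The TIN variant is this package's own concrete definition of
  progressive densification; it will not byte-match any particular
  proprietary implementation, only the behavior class.
- Greedy matching can in principle differ from the optimal assignment on
  pathological geometries (near-tied distances at the cap); at plantation
  spacing this does not occur, and the tests bound it on small instances.
- Crown delineation assumes crowns are star-shaped around the apex at
  raster resolution; heavily interlocking or leaning crowns violate this.
- The NGRDI/Otsu split assumes a bimodal scene; a cloud that is nearly
  all vegetation (or all ground) yields a threshold inside the single
  mode, which is flagged by the class-imbalance warning, not prevented.
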