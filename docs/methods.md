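# Methods

This note documents the models, parameters and numerical choices behind
`xrfseed`, and what the synthetic fixtures do and do not demonstrate.

## Input model

The package consumes the image products of an upstream μ-XRF quantification
step: an H×W×3 RGB composite of the scanned array and one H×W float map per
element on the same pixel grid. Map units are treated as opaque (the
upstream software reports semi-quantitative concentrations whose units
depend on its calibration assumptions); all element traits are arithmetic
means over seed pixels, so they scale linearly with whatever units arrive.
Coordinates are 0-based (row, col) with the origin top-left throughout.
RGB inputs deeper than 8 bits are max-normalised to 0–255; this preserves
the relative contrast the segmentation relies on while making the pixel
classifier's feature ranges independent of export depth.

## Accession segmentation

Tape patches are far lighter than the scan background while their a\*/b\*
chroma is unremarkable, so segmentation thresholds the L\* channel alone.
The threshold is Li's minimum cross-entropy method (`skimage.filters.
threshold_li`); it is exactly shift-invariant (the implementation shifts the
channel to its minimum before iterating), which the property tests assert.
Refinement is closing → hole filling → opening with disk structuring
elements of radius 3 and 2 px. The radii are our choice: closing at 3 px
bridges scan-line dropouts inside patches without merging adjacent patches
(patch gaps are tens of pixels), and opening at 2 px removes burrs without
eroding patch corners noticeably. Both are exposed in the config.
A constant-lightness frame has no threshold; it yields an empty mask plus a
warning rather than aborting a batch run.

Patches that the morphology cannot separate are cut along polyline files
(JSON lists of (row, col) vertices) instead of an interactive tool: files
are reproducible and testable. Polylines are rasterised 1 px wide with an
extra 4-neighbour pixel at every diagonal Bresenham step, so a cut always
blocks 8-connectivity.

## Numbering

Regions are numbered top-to-bottom, left-to-right. Row bands come either
from row-delimiter polylines (each line's mean row is a band boundary) or
automatically by splitting the sorted centroid rows at the `n_rows − 1`
largest gaps. Within a band, regions sort by centroid column; ties break by
centroid row, then label value. The ordering is therefore a pure function
of region geometry — relabeling the mask cannot change the numbering, which
the tests verify by permuting label IDs.

## Pixel classification

Seed masking is a binary per-pixel classification on six features: R, G, B
scaled to [0, 1] and hexcone H, S, V (H as a fraction of the hue circle).
Four classifiers are trained on a user-supplied labeled pixel table split
8:2 (train floor(0.8 n), test the remainder, permutation fixed by the run
seed): 5-nearest-neighbours and an RBF SVM (C = 1, gamma = 'scale'), both on
z-scored features fitted on the training split only; a 100-tree random
forest; and 100 rounds of gradient-boosted trees (histogram method, single
thread, fixed seed — this keeps reruns bit-identical). Hyperparameters are
deliberately plain defaults; the feature space is low-dimensional and the
classes are strongly separated in practice, so model choice matters more
than tuning. Selection is by F1 on the held-out split, ties broken by
accuracy and then by a fixed model order (knn, svm, random_forest,
xgboost). Metrics derive from the positive-class confusion matrix; a zero
denominator reports the metric as 0 with an `undefined` flag rather than
NaN.

## Adherent splitting

The splitter converts the raw seed mask into one label per seed:

1. **Watershed.** Markers are local maxima of the Euclidean distance
   transform separated by at least the splitting footprint, default 25 px;
   the watershed floods the negated distance map inside the mask. The
   footprint is interpreted as the minimum marker separation because that is
   the one scalar knob of a marker-controlled watershed; it should be set
   just below the typical seed's major-axis length in pixels.
2. **Undersize filter.** Objects smaller than 0.75× the median object area
   (median over all objects, computed before any removal) are discarded as
   over-segmentation fragments. A lone object equals the median and is
   never removed.
3. **Convex-defect cutting.** Objects larger than 1.25× the median area are
   treated as unresolved clumps. For each: the convex hull is computed, the
   hull-minus-region defect blobs of ≥ 3 px locate candidate necks, the
   Harris corner response (k = 0.04) along the region contour picks one
   representative inflection point per defect (ties broken lexicographically
   by (row, col)), and the closest pair of representatives from distinct
   defects is joined by a 1-px 4-connected cut line. With a single defect
   blob the two deepest adjacent contour points (depth = distance to the
   hull boundary, minimum 3 px apart) are joined instead. A cut is kept
   only if it increases the component count. The flag-and-cut loop repeats
   (max 10 iterations) until nothing is flagged, then the undersize filter
   runs once more with a freshly recomputed median — recomputed, because
   cutting changes the area distribution the threshold refers to.

Cuts only remove pixels, so labels are always a subset of the input mask,
and each productive cut strictly increases the component count, which
bounds the iteration. Oversized objects that survive the cap are reported
in the run metadata with a warning.

The median-area statistics assume a unimodal object-size distribution, i.e.
seeds of one species imaged at one resolution. Mixing species with very
different seed sizes in one image would break both filters; process such
images per accession subset instead.

## Trait extraction

Area is the pixel count. Length and width are the major/minor axis lengths
of the moment-equivalent ellipse (a maximum-Feret variant is available via
`method="feret"`); eccentricity is √(1 − W²/L²), which is 0 for a circle
and approaches 1 for elongated seeds. Roundness is 4πA/P², clamped to ≤ 1.

The perimeter needs care: naive pixel-edge counting overestimates a digital
disk's circumference by up to 4/π, and even the raw marching-squares
contour overestimates it by ~5 % through staircase steps. We measure the
sub-pixel 0.5-level contour and simplify it with a Douglas-Peucker
tolerance of 1 px before summing segment lengths. On rasterised references
this lands within 0.5 % for disks and ellipses (disk roundness ≈ 0.99) while
preserving true corners (square roundness ≈ 0.79 ≈ π/4), so no
shape-specific calibration constant is needed. Degenerate thin regions are
guarded by clamping axis lengths to ≥ 1 px.

Seeds are assigned to the accession whose mask contains their centroid —
simple, deterministic, and correct whenever seeds lie on their patch, which
the array geometry guarantees; orphans are emitted with accession index 0
and a log message rather than dropped. Seed indices count in reading order
of centroids within each accession.

## Evaluation

IoU and Dice are computed on foreground unions for whole-image scores and
on greedily matched object pairs (descending pairwise IoU, one-to-one) for
per-object scores; unmatched truth objects score 0 in the per-seed mean, so
merges are penalised rather than hidden. Two empty masks score 1 by
definition (flagged); the real workflow never produces this case, but the
definition keeps the metrics total. `agreement` wraps Pearson's r and r²
for cross-method trait comparisons.

## Synthetic data

The generator emulates the geometry that matters to the algorithms: bright
bluish-white tape rectangles (L\* near maximum) on a dark background, seeds
as filled rotated ellipses in a contrasting color, semi-axes drawn from
21–25 px × 13.5–16.5 px — the narrow size spread of a single-species seed
lot, which is exactly the regime the median-area filters assume. A chosen
fraction of seed pairs is placed adherent, with boundary-to-boundary
overlap of 5–30 % of the smaller minor axis and rasterised contact verified
explicitly; isolated seeds are verified non-touching. All seeds of one
accession share one true element composition (one accession is one
genotype), drawn from element-specific plausible ranges (e.g. K and P in
the thousands of μg/g, As and Se well below 1 μg/g). Element maps hold the
true mean at every seed pixel plus optional Gaussian noise clipped at 0;
true means are quantised to float32 so that "noiseless fixtures recover
means exactly" is well-defined against float32 map storage. A single RNG
seeded once per call makes every fixture bit-reproducible.

What the fixtures do **not** emulate: within-seed concentration gradients,
detector noise structure, penetration-depth attenuation of light elements,
tape wrinkles and specular glints, or handwritten annotations. Passing
tests therefore demonstrate the correctness of the segmentation, numbering,
splitting and measurement logic under controlled geometry — not the
end-to-end accuracy on beamline images, which depends on classifier
training quality and the physics of the signal.

## Problem sizes and determinism

Tests and the acceptance script use a 2 × 3 accession array with 5 seeds
each (30 seeds, 3 adherent pairs) for end-to-end runs, 100 independent
600×600 px scenes of 8 isolated seeds plus 2 adherent pairs and 1 triple
for the splitter, 200 random ellipses for morphology recovery, and 1000
random 16×16 mask pairs for the metric oracles — sizes chosen so the whole
suite exercises every code path in well under a minute of compute per
component. Every stochastic step (layout, scenes, dataset split, forest
and boosting seeds) flows from one recorded seed, and reruns of the
pipeline with the same config produce byte-identical trait tables.
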