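# Methods

This note records the models, conventions, and numerical choices behind
histotile, in the order data flows through the package.

## Coordinate and pyramid model

All geometry lives in the **level-0 pixel frame**: origin at the slide's
top-left corner, x rightward, y downward, 0-based indices, half-open
extents (`[x, x+w)`). A pyramid level k is a copy of the slide at
`1/downsamples[k]` scale, with `downsamples[0] = 1` and downsample
factors strictly increasing. `read_region` follows the OpenSlide calling
convention — level-0 origin, level-local size — so tiling code computes
origins once and reads at any level. Reads beyond the slide edge are
filled opaque white (255,255,255), matching slide background, so edge
tiles remain usable rather than erroring.

Physical units: a length of n pixels at level k corresponds to
`n · mpp_x · downsamples[k]` microns, where `mpp_x` is the level-0
microns-per-pixel. MPP and objective power are read from TIFF resolution
tags and a JSON ImageDescription key written by the synthetic generator;
when a file carries neither, the fields are `None` and operations that
need them fail with an explicit error — metadata is never defaulted,
because a silently assumed 0.25 µm/px corrupts every downstream physical
size. For the same reason, mapping a requested magnification to a level
requires an **exact** downsample match (within 1e-6 relative); there is
no nearest-level fallback.

## ROI model

A region of interest is a simple closed polygon (≥3 vertices, implicit
closure, positive area, no self-intersection) with a class label. The
self-intersection check is an O(n²) segment-pair test so the error can
name the offending edge pair; vertex lists that are entirely collinear
are reported as zero-area rather than self-intersecting. Self-crossing
outlines are rejected rather than reinterpreted by a fill rule: an
annotator's bow-tie is almost always a slip of the hand, and silently
choosing an interior risks mislabelled tissue. Points on the boundary
count as *inside* (even–odd rule plus an explicit on-segment test),
consistent with area-based tile inclusion. Edits (move/insert/delete
vertex) produce a new validated polygon or are rejected whole; ROIs are
immutable values.

Overlapping ROIs of different labels are permitted; each generates tiles
independently. The on-disk annotation format does not forbid it and the
package has no basis for choosing a winner.

## Tile grid and inclusion

The grid for one ROI is anchored at the floored minimum corner of its
bounding box and steps by the tile's level-0 footprint
(`side_px · downsample`, snapped to an integer with a logged warning for
non-integer downsamples). Anchoring to the ROI rather than the slide
keeps the grid deterministic, local, and invariant to unrelated
annotations. Candidates are emitted in row-major order with their exact
overlap fraction: area(polygon ∩ tile square) / tile area, computed by
exact polygon clipping (shapely), not rasterisation.

Both inclusion modes share that single primitive: *full containment* is
`overlap ≥ 1 − 1e-9` (the tolerance absorbs floating-point dust in the
clipped area of an exactly-covered tile), *minimum overlap* is
`overlap ≥ t` for user-set `t ∈ (0, 1]`. The overlap criterion is an
**area fraction** — this is the package's documented interpretation of
"degree of overlapping" — and ties are kept. Manual overrides are applied
after rule selection and recorded on the tile (`added`/`removed`) so an
exported manifest distinguishes hand-picked tiles from rule-selected
ones. Consequences that follow from this design and are enforced by the
property tests: grids at different levels with the same physical
footprint are identical in level-0 terms; kept-sets shrink monotonically
as the threshold rises; tiles of one ROI/configuration are pairwise
disjoint.

## Cellularity filter

Cellularity is the fraction of a tile's area covered by cell nuclei, and
the filter keeps tiles with `cellularity ≥ threshold` (default 0.65 —
the operating point used for the reference datasets; "at least" means
ties are kept). Area fraction, not nucleus count, is the scored quantity.

The default detector is a classical stain-deconvolution pipeline chosen
so the package works offline with no trained weights: RGB → optical
density → Ruifrok–Johnston H&E unmixing (scikit-image's `rgb2hed`) →
hematoxylin channel → threshold → remove objects < `min_object_px`
(default 16 px) → fill holes < `min_object_px`. The threshold is
`max(od_threshold, Otsu)` when the channel has contrast and the absolute
floor `od_threshold` (default 0.05 OD) alone for featureless tiles: a
uniform pale tile maps to all-background, a uniformly hematoxylin-dark
tile to all-nucleus, and Otsu never invents nuclei in blank tiles by
splitting noise. Hole filling is deliberately size-bounded: in tiles
near 90% coverage the residual background forms large enclosed pockets
that unbounded filling would swallow, inflating the score by >0.1.

Detectors are pluggable via a registry keyed by name. The ground-truth
detector (synthetic slides only) crops the known level-0 nuclei mask at
the tile footprint, block-reducing by per-block majority for tiles at
higher levels; it is the oracle the filter tests compare against. A
StarDist adapter is registered behind the same interface and raises a
configuration error when the stardist package is absent; nothing else in
the package depends on it.

## Dataset layout, recovery, splits

Export writes `out/<slide_id>/images/tile_%06d.<ext>` plus
`descriptions/{rois.csv, tiles.csv, manifest.json}`. Schemas (UTF-8,
RFC 4180):

* `rois.csv`: `roi_id,label,n_vertices,vertices,bbox_x,bbox_y,bbox_w,bbox_h`
  with vertices encoded `"x1 y1;x2 y2;…"`;
* `tiles.csv`: `tile_id,roi_id,label,level,origin_x,origin_y,side_px,overlap_fraction,cellularity,filename`.

Numbering starts at 0 in tile order, zero-padded to 6 digits for stable
lexicographic sorting. PNG is lossless (crops are bit-identical to
`read_region` output); JPEG quality is fixed at 90 so a given dataset is
byte-reproducible per format. Coordinates round-trip exactly; real-valued
fractions to 6 decimals. A pre-existing slide directory is refused
without an explicit overwrite flag, protecting earlier annotations from
accidental duplication, and annotation recovery is implemented from the
descriptions CSVs (this package's convention). Loading validates
referential integrity (every tile's ROI must exist, labels must match)
and reports parse failures with file and line.

Splits are computed at **slide granularity** because each slide
corresponds to one patient; assigning tiles independently would leak
near-duplicate tiles of one patient across train and test and inflate
every metric. Slides are shuffled by a seeded generator and cut at
`round(n·f_train)` / `round(n·f_val)`, remainder test (so 5 slides at
60/20/20 give 3/1/1). Per-class subsampling draws without replacement
from each label with a seeded generator, preserving record order; it
exists to cut the heavy within-slide correlation of large tile sets.

## Augmentations

Six families — gaussian blur, right-angle rotations/flips, contrast,
saturation, brightness, hue-shift — applied in spec order with all
randomness drawn from one seeded generator: the same (image, spec) pair
is bit-identical across runs. Named combinations: mix1 =
rotations/flips + blur; mix2 = mix1 + brightness + contrast; mix3 = all
six.

Default parameter ranges are the package's own conventional magnitudes
(no authoritative values exist for this workflow) and are fully
configurable: blur σ ~ U(0, 2) px; brightness/contrast/saturation
factors ~ U(0.7, 1.3); hue delta ~ U(−0.1, 0.1) turns. Hue-shift
rotates every pixel's hue by the same amount on the HSV wheel with
wrap-around, preserving saturation and value to within ±1 unit of 8-bit
quantisation — exact on fully saturated pixels, so the six
primary/secondary colours map onto each other under k/6-turn shifts.
Rotations are multiples of 90°; for non-square inputs only 0°/180° are
drawn so output dimensions always equal input dimensions (tiles are
square, so the full set applies in practice).

## Evaluation

Tile metrics are one-vs-rest: for class c, every other class is
negative, giving sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP), F1 = 2·sens·prec/(sens+prec), plus overall
accuracy and the full confusion matrix. Aggregates are **macro**
(unweighted) means over classes — the package always emits the per-class
values alongside, so any other weighting can be recomputed. A ratio with
a zero denominator (class absent from truth or predictions) is NaN,
excluded from macro means, and logged; it is not silently zeroed because
0 and "undefined" support different conclusions.

Slide-level labels are majority votes over the slide's tile predictions.
Ties are resolved by the highest summed class probability when
probabilities are present, else by the lexicographically smallest tied
label, and are always flagged — tie-handling is this package's explicit
convention, and flagged so ambiguous slides are visible downstream.

Training support models intra-epoch validation: with very large tile
sets a full epoch moves the weights too far for end-of-epoch early
stopping to react, so validation runs k times per epoch (default 8) at
steps `floor(i·steps/k)`, and early stopping fires after `patience`
(default 5) consecutive checks without strict improvement
(`score > best + min_delta`, `min_delta` default 0 — an exact tie counts
as non-improvement). The per-epoch reading of the validation cadence is
a documented interpretation and both k and the patience are parameters.

## Synthetic slides

The generator emulates exactly what the pipeline consumes: a pyramid
with known downsamples (higher levels are box-filtered means of level 0,
matching the read-consistency oracle used in tests), MPP/objective
metadata, an eosin-pink background (230,180,200), hematoxylin-violet
nuclei (70,40,110), and a level-0 binary ground-truth mask that is by
construction the union of the drawn ellipses (the colour image gets a
1-px softened rim; the mask stays hard).

Nuclei are placed by seeded rejection sampling against a coarse density
map: ellipses with radii in `nucleus_radius_range` land at uniform
positions in each cell until the cell's measured mask coverage is within
±0.03 of target; draws that would overshoot by more than the tolerance
are rejected, and an attempt cap (20 000/cell) is logged if reached.
Densities above 0.9 are refused — random elliptical packing cannot
reliably reach them — which still leaves the 0.65 filter threshold
exercisable from both sides. Defaults are chosen once as realistic for a
40× H&E scan: 0.25 µm/px, objective 40, radii 8–14 px (nucleus diameters
4–7 µm), uniform 30% coverage on a 2×2 map.

What the generator does **not** emulate: tissue texture, stain
variability, scanner artefacts (blur, folds, pen marks), or vendor file
formats. Passing tests therefore demonstrate the geometric, bookkeeping,
and thresholding logic exactly, and the stain-deconvolution detector's
behaviour on idealised H&E contrast; they do not certify detector
accuracy on real tissue, where chromatin texture and stain variation
make segmentation far harder.

## Problem sizes and numerical choices

Tests and the acceptance script use slides of 256–1024 px base with 2–4
levels and 4-cell density maps — large enough that every code path
(multi-level reads, partial tiles, threshold straddling) is exercised
with margins, small enough to regenerate fresh on every run. The
geometry oracle checks ≥200 random polygon/tile pairs against 512×512
sub-pixel point sampling (agreement within 1e-3; the sampling oracle is
matplotlib-path-based and independent of the shapely clipping route).
Key tolerances: containment 1e-9; magnification match 1e-6 relative;
probability row sums 1e-6; generator coverage ±0.03 per cell; CSV
fraction round-trip 6 decimals.

## Known limitations

* Vendor formats require the optional OpenSlide backend; without it the
  package is pyramidal-TIFF-only (a warning is logged). DICOM-WSI is
  untested.
* Slides are held in memory per level; this is comfortable for synthetic
  and test-scale slides but a true 40× gigapixel slide should be read
  through the OpenSlide backend rather than the in-memory TIFF path.
* Non-integer downsamples produce snapped (approximate) level-0
  footprints; exact grid equivalence across levels is guaranteed only
  for integer downsamples.
* No multi-polygon ROIs with holes, no strided/overlapping tile grids,
  no stain normalisation, and no artefact (blur/fold/pen) classifiers.
* The default nuclei detector is a classical pipeline; on real H&E
  tiles it should be treated as a coarse cellularity proxy, with
  StarDist (or any registered detector) substituted where instance-level
  accuracy matters.
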