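# histotile

Turn whole-slide histology images and polygon region-of-interest
annotations into labelled, quality-filtered tile datasets — the
preprocessing that stands between a scanned H&E slide and a trainable
image classifier — plus the evaluation machinery used once a classifier
exists: tile-level one-vs-rest metrics, tile→slide majority voting, and
intra-epoch early-stopping helpers.

It is written for pathologists' collaborators and computational-pathology
engineers who need this pipeline as a *library* (headless, scriptable,
testable) rather than as a GUI. A thin `histotile` command-line interface
covers the common one-shot operations.

## What it does

A whole-slide image (WSI) is a gigapixel scan stored as an image pyramid:
level 0 at full resolution (e.g. 40×, 0.25 µm/px) and successively
downsampled copies above it. Most of a slide is background or
non-informative tissue, so training data is built by:

1. **ROI annotation** — closed, simple polygons in level-0 pixel
   coordinates, each carrying a class label (`histotile.roi`);
2. **tiling** — a square grid (default 512 px) laid over each ROI's
   bounding box at a chosen pyramid level; a tile is kept when its
   footprint-area overlap with the polygon reaches a threshold
   (full containment, or a user-set minimum overlap fraction), with
   manual per-tile add/remove overrides (`histotile.tiling`);
3. **cellularity filtering** — each tile is scored by the fraction of its
   area covered by detected cell nuclei, and tiles under a threshold
   (default 0.65, i.e. at least 65% nuclear area) are dropped. The
   default detector is a classical stain-deconvolution pipeline
   (optical density → hematoxylin channel → Otsu + absolute OD floor →
   morphological cleanup); detectors are pluggable and a StarDist adapter
   registers itself when that package is installed
   (`histotile.cellularity`);
4. **export** — crops plus `rois.csv`/`tiles.csv` descriptions in a
   per-slide `images/` + `descriptions/` layout that can be loaded back
   exactly to resume annotation, patient-level train/val/test splitting
   (60/20/20 by default — all tiles of one patient stay in one split),
   and per-class subsampling (`histotile.dataset`);
5. **training support** — seeded, bit-reproducible augmentations
   (blur, right-angle rotations/flips, brightness, contrast, saturation,
   hue-shift, and the named combinations mix1/mix2/mix3), a k-per-epoch
   validation schedule, and early stopping after 5 consecutive
   non-improving checks (`histotile.augment`, `histotile.evaluation`);
6. **evaluation** — per-class sensitivity TP/(TP+FN), specificity
   TN/(TN+FP), precision TP/(TP+FP), F1 = 2·sens·prec/(sens+prec)
   (one-vs-rest), overall accuracy, and slide-level labels by majority
   voting over each slide's tiles (`histotile.evaluation`).

Because real WSIs are huge and vendor-locked, the package ships a
synthetic-slide generator (`histotile.synthetic`): H&E-like pyramids with
a pale eosin background, hematoxylin-dark elliptical nuclei placed to hit
a target coverage per region, full metadata, and an exact level-0
ground-truth nuclei mask. Every capability above is testable offline
against it.

Pyramidal TIFF/BigTIFF is always readable; vendor formats (.svs, .ndpi,
…) are read through the OpenSlide backend when it is installed.

## A worked example

`examples/03_filter_and_export.py` builds a 512² synthetic slide whose
four quadrants have 20/60/70/90% true nuclear coverage, tiles it with
four 256-px tiles, and filters at the 0.65 threshold:

```
tile  true-coverage  detector-estimate  kept(>=0.65)
  0      0.177          0.176            no
  1      0.574          0.577            no
  2      0.672          0.677            yes
  3      0.870          0.879            yes
exported 2 tiles -> .../synthetic-13/{images,descriptions}
recovered annotation: 1 ROI, 2 tile records (round-trip exact: True)
patient-level split: {'train': 12, 'val': 4, 'test': 4}
```

The stain-deconvolution estimates track the generator's ground truth to
within ~0.01 here, so exactly the two quadrants at or above 65% nuclear
coverage survive; the exported dataset reloads losslessly, and 20
patients split 12/4/4 at the default 60/20/20 fractions. The other
example scripts cover pyramid I/O (`01`), ROI tiling and manual overrides
(`02`), and augmentation + two-level evaluation (`04`); each prints what
it computes and can be run directly with `python examples/<name>.py`.

CLI equivalent of the core loop:

```sh
histotile synth --size 1024 --levels 1,4 --density 0.7 --out slide.tiff
histotile tile --slide slide.tiff --rois rois.csv --side 512 --out tiles.csv
histotile filter --slide slide.tiff --tiles tiles.csv --rois rois.csv \
    --threshold 0.65 --out kept.csv
histotile export --slide slide.tiff --rois rois.csv --tiles kept.csv --out dataset/
histotile eval --predictions preds.csv --out-prefix metrics
```

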