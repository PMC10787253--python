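"""Cellularity scoring: keep only tiles rich in cell nuclei.

Histology slides contain large stretches of background, fat, or loose
stroma that carry little signal for a tissue classifier.  Each tile is
therefore scored by its *cellularity* — the fraction of its area covered by
detected cell nuclei — and tiles under a threshold (0.65 by default, i.e.
at least 65% of the tile area covered by nuclei) are excluded from the
dataset.

Detection is pluggable behind a small registry so more sophisticated
segmenters can be slotted in.  Three detectors ship with the package:

``stain_deconvolution`` (default)
    A classical pipeline needing no trained weights: RGB is converted to
    optical density and unmixed into hematoxylin/eosin/DAB channels
    (Ruifrok–Johnston colour deconvolution); nuclei are the
    hematoxylin-dark pixels above an absolute OD floor, refined by Otsu's
    threshold when the channel has contrast, then cleaned by small-object
    removal and hole filling.

``ground_truth``
    Reads the known nuclei mask of a synthetic slide (see
    :mod:`histotile.synthetic`); the exact oracle used in testing.

``stardist``
    Adapter for the StarDist deep instance segmenter, registered only when
    that package is importable; the union of predicted instances is the
    nuclei mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from skimage.color import rgb2hed
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .errors import ConfigurationError
from .pyramid import RasterImage, SlidePyramid, read_region
from .tiling import TileSpec


@dataclass(frozen=True)
class NucleiMask:
    """Binary nucleus/background mask aligned to a tile's raster."""

    mask: np.ndarray  # H x W bool
    detector_name: str

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class DetectorSpec:
    """A detector choice by name, with its keyword parameters."""

    name: str
    parameters: dict = field(default_factory=dict)


class Detector:
    """A nucleus segmenter: maps a tile image to a :class:`NucleiMask`.

    ``tile`` is passed so detectors that need slide coordinates (the
    ground-truth oracle) can locate the image on the slide; image-only
    detectors ignore it.
    """

    name: str = "base"

    def segment(self, image: RasterImage, tile: TileSpec | None = None) -> NucleiMask:
        raise NotImplementedError


class StainDeconvolutionDetector(Detector):
    """Classical H&E nuclei segmentation via colour deconvolution.

    Parameters
    ----------
    od_threshold:
        Absolute hematoxylin optical-density floor (default 0.05).  Pixels
        below it are never nuclei; a featureless pale tile therefore maps
        to an all-background mask, and a uniformly hematoxylin-dark tile to
        an all-nucleus mask.
    min_object_px:
        Connected components smaller than this are removed (default 16).
    """

    name = "stain_deconvolution"

    def __init__(self, od_threshold: float = 0.05, min_object_px: int = 16) -> None:
        if od_threshold < 0:
            raise ConfigurationError(f"od_threshold must be >= 0, got {od_threshold}")
        if min_object_px < 0:
            raise ConfigurationError(f"min_object_px must be >= 0, got {min_object_px}")
        self.od_threshold = float(od_threshold)
        self.min_object_px = int(min_object_px)

    def segment(self, image: RasterImage, tile: TileSpec | None = None) -> NucleiMask:
        hema = rgb2hed(image.pixels)[:, :, 0]
        cut = self.od_threshold
        # Otsu refines the cut only when the channel actually has contrast;
        # on a uniform tile it would split noise into fake classes.
        if hema.max() - hema.min() > 1e-6:
            cut = max(cut, threshold_otsu(hema))
        mask = hema >= cut
        if self.min_object_px > 1:
            # components strictly smaller than min_object_px are dropped,
            # and only comparably small holes are filled: in nucleus-dense
            # tiles the residual background forms large enclosed pockets
            # that must not be swallowed into the nucleus area
            mask = remove_small_objects(mask, max_size=self.min_object_px - 1)
            mask = remove_small_holes(mask, max_size=self.min_object_px - 1)
        return NucleiMask(mask=mask, detector_name=self.name)


class GroundTruthDetector(Detector):
    """Oracle detector backed by a known level-0 nuclei mask.

    Used with synthetic slides, where the exact union of drawn nucleus
    ellipses is available; the mask is cropped at the tile's level-0
    footprint and block-reduced to the tile raster when the tile lives at
    a higher pyramid level.
    """

    name = "ground_truth"

    def __init__(self, nuclei_mask: np.ndarray) -> None:
        self.nuclei_mask = np.asarray(nuclei_mask, dtype=bool)

    def segment(self, image: RasterImage, tile: TileSpec | None = None) -> NucleiMask:
        if tile is None:
            raise ConfigurationError(
                "ground_truth detector needs the tile to locate the image on the slide"
            )
        x, y = tile.origin_l0
        f = tile.footprint_l0
        H, W = self.nuclei_mask.shape
        crop = np.zeros((f, f), dtype=bool)
        x0, x1 = max(x, 0), min(x + f, W)
        y0, y1 = max(y, 0), min(y + f, H)
        if x0 < x1 and y0 < y1:
            crop[y0 - y : y1 - y, x0 - x : x1 - x] = self.nuclei_mask[y0:y1, x0:x1]
        side = tile.side_px
        if side != f:
            if f % side:
                raise ConfigurationError(
                    f"footprint {f} not an integer multiple of tile side {side}"
                )
            d = f // side
            # majority vote per block keeps the mask binary and area-faithful
            crop = crop.reshape(side, d, side, d).mean(axis=(1, 3)) >= 0.5
        return NucleiMask(mask=crop, detector_name=self.name)


class StarDistDetector(Detector):  # pragma: no cover - optional dependency
    """Adapter for StarDist instance segmentation (optional dependency)."""

    name = "stardist"

    def __init__(self, model_name: str = "2D_versatile_he", prob_thresh: float | None = None):
        try:
            from stardist.models import StarDist2D  # type: ignore
        except ImportError as exc:
            raise ConfigurationError(
                "the 'stardist' detector requires the stardist package, "
                "which is not installed"
            ) from exc
        self._model = StarDist2D.from_pretrained(model_name)
        self._prob_thresh = prob_thresh

    def segment(self, image: RasterImage, tile: TileSpec | None = None) -> NucleiMask:
        from csbdeep.utils import normalize  # type: ignore

        labels, _ = self._model.predict_instances(
            normalize(image.pixels), prob_thresh=self._prob_thresh
        )
        return NucleiMask(mask=labels > 0, detector_name=self.name)


DetectorFactory = Callable[..., Detector]

_REGISTRY: dict[str, DetectorFactory] = {
    "stain_deconvolution": StainDeconvolutionDetector,
    "ground_truth": GroundTruthDetector,
    "stardist": StarDistDetector,
}


def register_detector(name: str, factory: DetectorFactory) -> None:
    """Register a detector factory under ``name`` (overwrites silently)."""
    _REGISTRY[name] = factory


def build_detector(spec: DetectorSpec) -> Detector:
    """Instantiate the detector named by ``spec`` with its parameters."""
    try:
        factory = _REGISTRY[spec.name]
    except KeyError:
        raise ConfigurationError(
            f"unknown detector {spec.name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(**spec.parameters)


def segment_nuclei_default(image: RasterImage, **params) -> NucleiMask:
    """Segment nuclei with the default stain-deconvolution detector."""
    return StainDeconvolutionDetector(**params).segment(image)


def cellularity_score(mask: NucleiMask) -> float:
    """Fraction of mask pixels classified as nucleus, in [0, 1]."""
    return float(mask.mask.mean())


#: The operating threshold used for the package's reference datasets:
#: a tile is kept when at least 65% of its area is covered by nuclei.
DEFAULT_CELLULARITY_THRESHOLD = 0.65


def filter_tiles(
    tiles: Sequence[TileSpec],
    pyr: SlidePyramid,
    detector: DetectorSpec | Detector,
    threshold: float = DEFAULT_CELLULARITY_THRESHOLD,
) -> tuple[list[TileSpec], list[TileSpec]]:
    """Score every tile's cellularity and split at ``threshold``.

    Each tile's image is read at its own level, segmented, and the score
    stored on the returned :class:`~histotile.tiling.TileSpec`.  A tile is
    kept when ``cellularity >= threshold`` (ties kept — "at least").
    Returns ``(kept, rejected)`` preserving input order; their union is the
    input.  An unknown detector name fails before any image is read.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    det = build_detector(detector) if isinstance(detector, DetectorSpec) else detector
    kept: list[TileSpec] = []
    rejected: list[TileSpec] = []
    for t in tiles:
        img = read_region(pyr, t.level, t.origin_l0, (t.side_px, t.side_px))
        score = cellularity_score(det.segment(img, tile=t))
        scored = replace(t, cellularity=score)
        (kept if score >= threshold else rejected).append(scored)
    return kept, rejected
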