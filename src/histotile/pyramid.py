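"""Read access to multi-resolution slide pyramids and unit/level conversions.

A whole-slide image (WSI) is stored as an image pyramid: level 0 holds the
full-resolution scan and each higher level a progressively downsampled copy,
so viewers and tiling code can work at the resolution they need without
touching gigapixels.  This module provides a uniform in-memory view of such
pyramids (:class:`SlidePyramid`), loaded from pyramidal TIFF/BigTIFF via
tifffile, or from vendor formats (.svs, .ndpi, ...) through openslide when
that backend is installed.

Coordinate conventions (used package-wide):

* the reference frame is **level-0 pixels**, origin at the top-left corner,
  x rightward, y downward, 0-based;
* extents are half-open: a region of width w starting at x covers
  ``[x, x+w)``;
* :func:`read_region` takes a level-0 origin and a size expressed in pixels
  *at the requested level* (the OpenSlide convention), so tiling code never
  converts origins between levels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MagnificationError, MetadataError, SlideFormatError

logger = logging.getLogger(__name__)

try:  # vendor-format backend, optional
    import openslide as _openslide  # type: ignore
except ImportError:  # pragma: no cover - backend not installed
    _openslide = None

#: Description key used to carry magnification metadata in TIFFs written by
#: :mod:`histotile.synthetic`.
DESCRIPTION_KEY = "histotile"

_VENDOR_SUFFIXES = {".svs", ".ndpi", ".mrxs", ".scn", ".bif", ".vms", ".vmu", ".svslide"}


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit RGB raster."""

    pixels: np.ndarray  # H x W x 3 uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.uint8)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected H x W x 3 RGB array, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SlidePyramid:
    """A multi-level slide image held in memory.

    Parameters
    ----------
    slide_id:
        Text stem of the source path (or a caller-chosen identifier).
    levels:
        Per-level H x W x 3 uint8 arrays, level 0 first (full resolution).
    mpp_x, mpp_y:
        Microns per pixel at level 0, when the source metadata provides
        them; ``None`` otherwise (never fabricated).
    objective_power:
        Nominal magnification of the level-0 scan (e.g. 40), when known.
    """

    slide_id: str
    levels: list[np.ndarray]
    mpp_x: float | None = None
    mpp_y: float | None = None
    objective_power: float | None = None
    downsamples: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.levels:
            raise SlideFormatError("pyramid has no levels")
        self.levels = [np.ascontiguousarray(lv, dtype=np.uint8) for lv in self.levels]
        for lv in self.levels:
            if lv.ndim != 3 or lv.shape[2] != 3 or min(lv.shape[:2]) < 1:
                raise SlideFormatError(f"level has invalid shape {lv.shape}")
        if not self.downsamples:
            w0 = self.levels[0].shape[1]
            self.downsamples = tuple(w0 / lv.shape[1] for lv in self.levels)
        self.downsamples = tuple(float(d) for d in self.downsamples)
        self._validate()

    def _validate(self) -> None:
        ds = self.downsamples
        if len(ds) != len(self.levels):
            raise SlideFormatError("downsamples and levels length mismatch")
        if abs(ds[0] - 1.0) > 1e-9:
            raise SlideFormatError(f"downsamples[0] must be 1, got {ds[0]}")
        if any(b <= a for a, b in zip(ds, ds[1:])):
            raise SlideFormatError(f"downsamples must be strictly increasing, got {ds}")
        w0, h0 = self.level_dims[0]
        for k, (w, h) in enumerate(self.level_dims):
            if abs(w - w0 / ds[k]) > 1 or abs(h - h0 / ds[k]) > 1:
                raise SlideFormatError(
                    f"level {k} dims {(w, h)} inconsistent with downsample {ds[k]}"
                )
        for v in (self.mpp_x, self.mpp_y):
            if v is not None and v <= 0:
                raise SlideFormatError(f"mpp must be positive, got {v}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def level_dims(self) -> tuple[tuple[int, int], ...]:
        """Per-level (width, height) in pixels."""
        return tuple((lv.shape[1], lv.shape[0]) for lv in self.levels)


def _parse_description(desc: str | None) -> dict:
    """Extract the histotile metadata dict from an ImageDescription string."""
    if not desc:
        return {}
    try:
        payload = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
    if isinstance(payload, dict) and DESCRIPTION_KEY in payload:
        inner = payload[DESCRIPTION_KEY]
        return inner if isinstance(inner, dict) else {}
    return payload if isinstance(payload, dict) else {}


def _mpp_from_resolution(page) -> float | None:
    """Microns per pixel from TIFF XResolution/ResolutionUnit tags."""
    tags = page.tags
    res = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if res is None or unit is None:
        return None
    num, den = res.value if isinstance(res.value, tuple) else (res.value, 1)
    if not num:
        return None
    pixels_per_unit = num / den
    unit_name = getattr(unit.value, "name", str(unit.value)).upper()
    microns_per_unit = {"CENTIMETER": 1e4, "INCH": 2.54e4}.get(unit_name)
    if microns_per_unit is None:
        return None
    return microns_per_unit / pixels_per_unit


def _open_tiff(path: Path) -> SlidePyramid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            pages = list(tf.pages)
            arrays = []
            for page in pages:
                arr = page.asarray()
                if arr.ndim == 2:
                    arr = np.stack([arr] * 3, axis=-1)
                if arr.ndim != 3 or arr.shape[2] < 3:
                    raise SlideFormatError(
                        f"{path}: page with shape {arr.shape} is not RGB"
                    )
                arrays.append(np.ascontiguousarray(arr[:, :, :3], dtype=np.uint8))
            desc_meta = _parse_description(pages[0].description)
            mpp_tag = _mpp_from_resolution(pages[0])
    except SlideFormatError:
        raise
    except Exception as exc:
        raise SlideFormatError(f"cannot read {path} as a pyramidal TIFF: {exc}") from exc

    # level 0 first, regardless of page order on disk
    arrays.sort(key=lambda a: -a.shape[1])
    mpp = desc_meta.get("mpp_x", mpp_tag)
    mpp_y = desc_meta.get("mpp_y", mpp_tag)
    pyr = SlidePyramid(
        slide_id=path.stem,
        levels=arrays,
        mpp_x=float(mpp) if mpp is not None else None,
        mpp_y=float(mpp_y) if mpp_y is not None else None,
        objective_power=(
            float(desc_meta["objective_power"])
            if desc_meta.get("objective_power") is not None
            else None
        ),
    )
    if pyr.n_levels == 1:
        logger.warning("%s: single-level image, no pyramid (accepted)", path)
    return pyr


def _open_vendor(path: Path) -> SlidePyramid:  # pragma: no cover - needs backend
    try:
        osl = _openslide.OpenSlide(str(path))
    except Exception as exc:
        raise SlideFormatError(f"backend cannot open {path}: {exc}") from exc
    with osl:
        levels = [
            np.asarray(
                osl.read_region((0, 0), k, osl.level_dimensions[k]).convert("RGB")
            )
            for k in range(osl.level_count)
        ]
        props = osl.properties
        mpp_x = props.get("openslide.mpp-x")
        mpp_y = props.get("openslide.mpp-y")
        obj = props.get("openslide.objective-power")
    return SlidePyramid(
        slide_id=path.stem,
        levels=levels,
        mpp_x=float(mpp_x) if mpp_x else None,
        mpp_y=float(mpp_y) if mpp_y else None,
        objective_power=float(obj) if obj else None,
    )


def open_slide(path: str | Path) -> SlidePyramid:
    """Open a pyramidal slide file and return its :class:`SlidePyramid`.

    Pyramidal TIFF/BigTIFF is always supported; vendor formats go through
    the openslide backend when it is installed.  Metadata fields that the
    file does not provide are left ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise SlideFormatError(f"no such file: {path}")
    if path.suffix.lower() in _VENDOR_SUFFIXES:
        if _openslide is None:
            logger.warning(
                "slide-I/O backend not installed; only pyramidal TIFF is readable"
            )
            raise SlideFormatError(
                f"{path}: vendor format {path.suffix} needs the openslide backend"
            )
        return _open_vendor(path)
    return _open_tiff(path)


def read_region(
    pyr: SlidePyramid,
    level: int,
    origin_l0: tuple[int, int],
    size: tuple[int, int],
) -> RasterImage:
    """Read a rectangular region at a given pyramid level.

    ``origin_l0`` is the top-left corner in level-0 pixels; ``size`` is
    (width, height) in pixels *at* ``level``, so the level-0 footprint is
    ``size * downsamples[level]``.  Pixels outside the slide are filled
    opaque white, matching the slide background, so edge tiles stay usable.
    """
    if not 0 <= level < pyr.n_levels:
        raise IndexError(f"level {level} out of range [0, {pyr.n_levels})")
    w, h = size
    if w <= 0 or h <= 0:
        raise ValueError(f"size must be positive, got {size}")
    ds = pyr.downsamples[level]
    lx = int(round(origin_l0[0] / ds))
    ly = int(round(origin_l0[1] / ds))
    arr = pyr.levels[level]
    out = np.full((h, w, 3), 255, dtype=np.uint8)
    src_x0, src_x1 = max(lx, 0), min(lx + w, arr.shape[1])
    src_y0, src_y1 = max(ly, 0), min(ly + h, arr.shape[0])
    if src_x0 < src_x1 and src_y0 < src_y1:
        out[src_y0 - ly : src_y1 - ly, src_x0 - lx : src_x1 - lx] = arr[
            src_y0:src_y1, src_x0:src_x1
        ]
    return RasterImage(out)


def level_for_magnification(pyr: SlidePyramid, mag: float) -> int:
    """Return the pyramid level whose resolution equals magnification ``mag``.

    Requires an exact downsample match (within 1e-6 relative): silently
    resampling to a nearest level would change the physical size of every
    tile and corrupt the exported dataset, so a mismatch is an error that
    lists the magnifications actually available.
    """
    if pyr.objective_power is None:
        raise MetadataError(
            f"{pyr.slide_id}: objective power unknown; cannot map magnification to level"
        )
    if mag <= 0:
        raise ValueError(f"magnification must be positive, got {mag}")
    target = pyr.objective_power / mag
    for k, ds in enumerate(pyr.downsamples):
        if abs(ds - target) <= 1e-6 * target:
            return k
    available = [pyr.objective_power / ds for ds in pyr.downsamples]
    raise MagnificationError(
        f"{pyr.slide_id}: no level at {mag}x; available magnifications: "
        + ", ".join(f"{m:g}x" for m in available)
    )


def pixels_to_microns(pyr: SlidePyramid, n_pixels: float, level: int = 0) -> float:
    """Convert a pixel length at ``level`` to microns, using level-0 MPP."""
    if not 0 <= level < pyr.n_levels:
        raise IndexError(f"level {level} out of range [0, {pyr.n_levels})")
    if pyr.mpp_x is None:
        raise MetadataError(
            f"{pyr.slide_id}: microns-per-pixel metadata absent; physical size unavailable"
        )
    return n_pixels * pyr.mpp_x * pyr.downsamples[level]
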