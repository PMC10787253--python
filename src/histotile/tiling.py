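"""Square tile grids inside a ROI, with area-overlap inclusion rules.

Tiles are the unit fed to downstream classifiers: square crops taken on a
regular, non-overlapping grid laid over the ROI's bounding box.  A tile is
specified by its pyramid level and side length at that level; its level-0
footprint is ``side_px * downsample`` so the same physical grid can be
expressed at any level (tiling with side s at level k is identical, in
level-0 terms, to side s*d_k at level 0).

Inclusion is decided by the fraction of the tile's footprint area covered
by the ROI polygon ("completely included" is overlap fraction 1 within
1e-9, so both rule modes share one geometric primitive).  The user can then
manually force-include or force-exclude individual tiles, e.g. when the
polygon strays over an artefact.

The grid is anchored at the floored minimum corner of the ROI bounding
box: deterministic, local to the ROI, and unaffected by other ROIs on the
slide.  Origins are snapped to integer level-0 pixels so exported images
are pixel-exact crops.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from shapely.geometry import Polygon, box

from .pyramid import SlidePyramid
from .roi import PolygonROI

logger = logging.getLogger(__name__)

Override = Literal["added", "removed"]


@dataclass(frozen=True)
class TileSpec:
    """One square tile: grid position, overlap with its ROI, and state.

    ``origin_l0`` is the integer level-0 coordinate of the top-left corner;
    the footprint is the half-open square
    ``[x, x+footprint_l0) x [y, y+footprint_l0)``.
    """

    tile_id: int
    roi_id: int
    level: int
    side_px: int
    origin_l0: tuple[int, int]
    footprint_l0: int
    overlap_fraction: float
    included: bool | None = None
    manual_override: Override | None = None
    cellularity: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0 + 1e-12:
            raise ValueError(f"overlap_fraction outside [0,1]: {self.overlap_fraction}")
        if self.cellularity is not None and not 0.0 <= self.cellularity <= 1.0:
            raise ValueError(f"cellularity outside [0,1]: {self.cellularity}")

    @property
    def footprint_box(self) -> tuple[float, float, float, float]:
        x, y = self.origin_l0
        return (x, y, x + self.footprint_l0, y + self.footprint_l0)


@dataclass(frozen=True)
class InclusionRule:
    """How candidate tiles are admitted into the dataset.

    ``full_containment`` keeps only tiles entirely inside the ROI;
    ``min_overlap`` keeps tiles whose ROI-overlap area fraction reaches
    ``min_overlap``.  The default threshold of 1.0 makes ``min_overlap``
    behave as containment until the user relaxes it.
    """

    mode: Literal["full_containment", "min_overlap"] = "min_overlap"
    min_overlap: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("full_containment", "min_overlap"):
            raise ValueError(f"unknown inclusion mode {self.mode!r}")
        if not 0.0 < self.min_overlap <= 1.0:
            raise ValueError(f"min_overlap must be in (0, 1], got {self.min_overlap}")


_CONTAINMENT_TOL = 1e-9

#: Default tile side in pixels; a common operating point for 40x H&E tiles.
DEFAULT_SIDE_PX = 512


def _footprint_l0(side_px: int, downsample: float) -> int:
    exact = side_px * downsample
    snapped = int(round(exact))
    if abs(exact - snapped) > 1e-9:
        logger.warning(
            "non-integer level-0 footprint %.4f px snapped to %d px "
            "(side %d, downsample %g); grid exactness not guaranteed",
            exact,
            snapped,
            side_px,
            downsample,
        )
    return max(snapped, 1)


def tile_overlap_fraction(roi: PolygonROI, tile: TileSpec) -> float:
    """Fraction of the tile footprint area covered by the ROI polygon.

    Computed by exact polygon clipping against the tile square, so the
    value is exact up to floating point (no rasterisation involved).
    """
    poly = Polygon(roi.vertices)
    x0, y0, x1, y1 = tile.footprint_box
    inter = poly.intersection(box(x0, y0, x1, y1))
    frac = inter.area / (tile.footprint_l0**2)
    return min(max(frac, 0.0), 1.0)


def generate_candidate_tiles(
    roi: PolygonROI,
    side_px: int,
    level: int,
    pyr: SlidePyramid,
    start_tile_id: int = 0,
) -> list[TileSpec]:
    """Lay the tile grid over the ROI bounding box and score each candidate.

    Returns candidates in row-major order (left to right, top to bottom)
    with ``overlap_fraction`` computed and ``included`` not yet set; pass
    the result to :func:`select_tiles`.  Tile ids are assigned
    progressively from ``start_tile_id``.
    """
    if side_px < 1:
        raise ValueError(f"side_px must be >= 1, got {side_px}")
    if not 0 <= level < pyr.n_levels:
        raise IndexError(f"level {level} out of range [0, {pyr.n_levels})")
    ds = pyr.downsamples[level]
    step = _footprint_l0(side_px, ds)
    min_x, min_y, bw, bh = roi.bbox
    ax, ay = math.floor(min_x), math.floor(min_y)
    poly = Polygon(roi.vertices)
    area = step * step
    tiles: list[TileSpec] = []
    tid = start_tile_id
    ny = max(1, math.ceil((min_y + bh - ay) / step))
    nx = max(1, math.ceil((min_x + bw - ax) / step))
    for iy in range(ny):
        for ix in range(nx):
            x, y = ax + ix * step, ay + iy * step
            inter = poly.intersection(box(x, y, x + step, y + step))
            frac = min(max(inter.area / area, 0.0), 1.0)
            tiles.append(
                TileSpec(
                    tile_id=tid,
                    roi_id=roi.roi_id,
                    level=level,
                    side_px=side_px,
                    origin_l0=(x, y),
                    footprint_l0=step,
                    overlap_fraction=frac,
                )
            )
            tid += 1
    return tiles


def select_tiles(candidates: Sequence[TileSpec], rule: InclusionRule) -> list[TileSpec]:
    """Set the ``included`` flag on every candidate according to ``rule``.

    Order is preserved; manual overrides (if any) are reset — selection
    reflects the rule alone.  Use :func:`apply_manual_overrides` afterwards.
    """
    threshold = (
        1.0 - _CONTAINMENT_TOL if rule.mode == "full_containment" else rule.min_overlap
    )
    return [
        replace(t, included=t.overlap_fraction >= threshold, manual_override=None)
        for t in candidates
    ]


def apply_manual_overrides(
    tiles: Sequence[TileSpec],
    add_ids: Iterable[int] = (),
    remove_ids: Iterable[int] = (),
) -> list[TileSpec]:
    """Force-include (``add_ids``) or force-exclude (``remove_ids``) tiles.

    Added tiles become included regardless of overlap fraction; removed
    tiles excluded likewise.  The override is recorded on the tile so the
    exported manifest distinguishes rule-selected from hand-picked tiles.
    """
    add, remove = set(add_ids), set(remove_ids)
    both = add & remove
    if both:
        raise ValueError(f"tile ids in both add and remove lists: {sorted(both)}")
    known = {t.tile_id for t in tiles}
    unknown = (add | remove) - known
    if unknown:
        raise KeyError(f"unknown tile ids: {sorted(unknown)}")
    out = []
    for t in tiles:
        if t.tile_id in add:
            t = replace(t, included=True, manual_override="added")
        elif t.tile_id in remove:
            t = replace(t, included=False, manual_override="removed")
        out.append(t)
    return out
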