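"""Labelled polygon regions of interest (ROIs).

An ROI is a simple closed polygon drawn over the level-0 pixel frame of a
slide, carrying a class label; every tile generated inside it inherits that
label.  Polygons are validated at construction: at least three vertices, no
repeated consecutive vertices, positive enclosed area, and no
self-intersection (a bow-tie outline would make "inside" ambiguous and risk
mislabelled tissue, so it is rejected outright rather than resolved by a
fill rule).

Vertex order is preserved as given; all geometry below is orientation-
agnostic.  Points on the polygon boundary count as inside, consistent with
area-based tile inclusion (a tile touching the border is not dropped on a
technicality).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from .errors import ROIValidationError

Vertex = tuple[float, float]


class LabelSet:
    """An ordered set of distinct class labels.

    Labels can be added and removed dynamically as annotation proceeds; a
    label that is in use by an ROI should not be removed by the caller.
    """

    def __init__(self, labels: Iterable[str] = ()) -> None:
        self._labels: list[str] = []
        for lab in labels:
            self.add(lab)

    def add(self, label: str) -> None:
        if not label:
            raise ValueError("label must be non-empty")
        if label not in self._labels:
            self._labels.append(label)

    def remove(self, label: str) -> None:
        self._labels.remove(label)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._labels)

    def __contains__(self, label: str) -> bool:
        return label in self._labels

    def __iter__(self):
        return iter(self._labels)

    def __len__(self) -> int:
        return len(self._labels)


def shoelace_area(vertices: Sequence[Vertex]) -> float:
    """Absolute polygon area by the shoelace formula, in level-0 px^2."""
    n = len(vertices)
    acc = 0.0
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        acc += x1 * y2 - x2 * y1
    return abs(acc) / 2.0


def _orient(ax, ay, bx, by, cx, cy) -> float:
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


def _on_segment(ax, ay, bx, by, px, py, eps=1e-12) -> bool:
    if abs(_orient(ax, ay, bx, by, px, py)) > eps * (
        1 + abs(ax) + abs(bx) + abs(px) + abs(ay) + abs(by) + abs(py)
    ):
        return False
    return min(ax, bx) - eps <= px <= max(ax, bx) + eps and min(ay, by) - eps <= py <= max(
        ay, by
    ) + eps


def _segments_cross(p1: Vertex, p2: Vertex, q1: Vertex, q2: Vertex) -> bool:
    """True if closed segments [p1,p2] and [q1,q2] share any point."""
    d1 = _orient(*q1, *q2, *p1)
    d2 = _orient(*q1, *q2, *p2)
    d3 = _orient(*p1, *p2, *q1)
    d4 = _orient(*p1, *p2, *q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 and d2 and d3 and d4:
        return True
    for (a, b, p) in (
        (q1, q2, p1),
        (q1, q2, p2),
        (p1, p2, q1),
        (p1, p2, q2),
    ):
        if _on_segment(*a, *b, *p):
            return True
    return False


def _all_collinear(verts: Sequence[Vertex], eps: float = 1e-12) -> bool:
    a, b = verts[0], verts[1]
    scale = 1 + max(abs(c) for v in verts for c in v)
    return all(abs(_orient(*a, *b, *p)) <= eps * scale * scale for p in verts[2:])


def _find_self_intersection(vertices: Sequence[Vertex]) -> tuple[int, int] | None:
    """Return the first pair of edge indices that improperly intersect."""
    n = len(vertices)
    edges = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            adjacent = j == i + 1 or (i == 0 and j == n - 1)
            if adjacent:
                # neighbours legitimately share one endpoint; any further
                # contact (collinear overlap, spike) is an intersection
                shared = edges[i][1] if j == i + 1 else edges[i][0]
                free_i = edges[i][0] if edges[i][1] == shared else edges[i][1]
                free_j = edges[j][1] if edges[j][0] == shared else edges[j][0]
                if free_i == free_j:  # full spike: edge retraces itself
                    return (i, j)
                if _on_segment(*edges[j][0], *edges[j][1], *free_i) or _on_segment(
                    *edges[i][0], *edges[i][1], *free_j
                ):
                    return (i, j)
                continue
            if _segments_cross(*edges[i], *edges[j]):
                return (i, j)
    return None


@dataclass(frozen=True)
class PolygonROI:
    """A validated labelled polygon in level-0 pixel coordinates.

    The polygon is implicitly closed (the last vertex connects back to the
    first).  Instances are immutable; use :func:`edit_roi` to derive
    modified copies.
    """

    roi_id: int
    vertices: tuple[Vertex, ...]
    label: str

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if self.roi_id < 0:
            raise ROIValidationError(f"roi_id must be >= 0, got {self.roi_id}")
        _validate_vertices(verts)

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, width, height) of the vertex bounding box."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return (min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))


def _validate_vertices(verts: Sequence[Vertex]) -> None:
    if len(verts) < 3:
        raise ROIValidationError(f"a polygon needs >= 3 vertices, got {len(verts)}")
    for i in range(len(verts)):
        if verts[i] == verts[(i + 1) % len(verts)]:
            raise ROIValidationError(f"consecutive duplicate vertex at index {i}")
    if _all_collinear(verts):
        raise ROIValidationError("polygon has zero enclosed area")
    bad = _find_self_intersection(verts)
    if bad is not None:
        raise ROIValidationError(
            f"polygon is self-intersecting: edge {bad[0]} "
            f"({verts[bad[0]]} -> {verts[(bad[0] + 1) % len(verts)]}) crosses edge {bad[1]} "
            f"({verts[bad[1]]} -> {verts[(bad[1] + 1) % len(verts)]})"
        )
    if shoelace_area(verts) <= 0.0:
        raise ROIValidationError("polygon has zero enclosed area")


def create_roi(
    vertices: Sequence[Vertex], label: str, roi_id: int, labelset: LabelSet | None = None
) -> PolygonROI:
    """Construct and validate a :class:`PolygonROI`.

    When ``labelset`` is given, ``label`` must be one of its members —
    this mirrors the annotation workflow where the class list is declared
    before regions are drawn.
    """
    if labelset is not None and label not in labelset:
        raise ROIValidationError(
            f"label {label!r} not in active label set {labelset.labels}"
        )
    return PolygonROI(roi_id=roi_id, vertices=tuple(vertices), label=label)


def polygon_area(roi: PolygonROI) -> float:
    """Enclosed area of the ROI in level-0 px^2 (absolute shoelace sum)."""
    return shoelace_area(roi.vertices)


def point_in_polygon(roi: PolygonROI, point: Vertex) -> bool:
    """Even-odd (ray casting) point membership; boundary points are inside."""
    px, py = float(point[0]), float(point[1])
    verts = roi.vertices
    n = len(verts)
    for i in range(n):
        if _on_segment(*verts[i], *verts[(i + 1) % n], px, py):
            return True
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


EditKind = Literal["move_vertex", "insert_vertex", "delete_vertex"]


def edit_roi(
    roi: PolygonROI,
    edit: EditKind,
    index: int,
    xy: Vertex | None = None,
) -> PolygonROI:
    """Return a new ROI with one vertex moved, inserted, or deleted.

    The edit is applied to a copy and re-validated; an edit that would
    break an invariant (fewer than 3 vertices, self-intersection, zero
    area) raises :class:`ROIValidationError` and leaves the original
    untouched.  ``insert_vertex`` inserts *before* position ``index``.
    """
    verts = list(roi.vertices)
    n = len(verts)
    if edit == "move_vertex":
        if not 0 <= index < n:
            raise IndexError(f"vertex index {index} out of range [0, {n})")
        if xy is None:
            raise ValueError("move_vertex requires a new coordinate")
        verts[index] = (float(xy[0]), float(xy[1]))
    elif edit == "insert_vertex":
        if not 0 <= index <= n:
            raise IndexError(f"insert index {index} out of range [0, {n}]")
        if xy is None:
            raise ValueError("insert_vertex requires a coordinate")
        verts.insert(index, (float(xy[0]), float(xy[1])))
    elif edit == "delete_vertex":
        if not 0 <= index < n:
            raise IndexError(f"vertex index {index} out of range [0, {n})")
        del verts[index]
    else:
        raise ValueError(f"unknown edit kind {edit!r}")
    return replace(roi, vertices=tuple(verts))
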