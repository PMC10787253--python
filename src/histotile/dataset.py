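"""Export tile datasets to disk, recover annotations, split and subsample.

The on-disk layout mirrors how annotation tools hand data to model
training: one directory per slide, holding an ``images/`` folder with the
tile crops named by a progressive number, and a ``descriptions/`` folder
with two CSVs — ``rois.csv`` (one row per polygon ROI) and ``tiles.csv``
(one row per exported tile, carrying its label, generating ROI, grid
position and cellularity).  A ``manifest.json`` sidecar repeats the same
information in machine-readable form.

Loading the descriptions back reconstructs the annotation exactly
(coordinates exact; real-valued fractions to 6 decimals), which is how a
half-finished annotation session is resumed without duplicating work.

Splits are computed at slide granularity — every slide corresponds to one
patient, and tiles of one patient must never straddle train/val/test or
the evaluation leaks — and per-class subsampling reduces the within-slide
correlation of very large tile sets.

CSV schemas (UTF-8, comma-separated, header row, RFC 4180 quoting):

* ``rois.csv``: roi_id,label,n_vertices,vertices,bbox_x,bbox_y,bbox_w,bbox_h
  with vertices encoded ``"x1 y1;x2 y2;..."``
* ``tiles.csv``: tile_id,roi_id,label,level,origin_x,origin_y,side_px,
  overlap_fraction,cellularity,filename
"""

from __future__ import annotations

import csv
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import IntegrityError, ManifestParseError
from .pyramid import SlidePyramid, read_region
from .roi import PolygonROI
from .tiling import TileSpec

ROIS_HEADER = ["roi_id", "label", "n_vertices", "vertices", "bbox_x", "bbox_y", "bbox_w", "bbox_h"]
TILES_HEADER = [
    "tile_id",
    "roi_id",
    "label",
    "level",
    "origin_x",
    "origin_y",
    "side_px",
    "overlap_fraction",
    "cellularity",
    "filename",
]

JPEG_QUALITY = 90  # fixed so jpeg exports are byte-reproducible


@dataclass(frozen=True)
class TileRecord:
    """One exported tile as recorded in ``tiles.csv``."""

    tile_id: int
    roi_id: int
    label: str
    level: int
    origin_l0: tuple[int, int]
    side_px: int
    overlap_fraction: float
    cellularity: float | None
    filename: str


@dataclass
class DatasetManifest:
    """In-memory mirror of one slide's exported images + descriptions."""

    slide_id: str
    rois: list[PolygonROI]
    tile_records: list[TileRecord]
    image_format: str

    def __post_init__(self) -> None:
        roi_ids = {r.roi_id for r in self.rois}
        labels = {r.roi_id: r.label for r in self.rois}
        names = [t.filename for t in self.tile_records]
        if len(names) != len(set(names)):
            raise IntegrityError(f"{self.slide_id}: duplicate tile filenames")
        for t in self.tile_records:
            if t.roi_id not in roi_ids:
                raise IntegrityError(
                    f"{self.slide_id}: tile {t.tile_id} references unknown ROI {t.roi_id}"
                )
            if t.label != labels[t.roi_id]:
                raise IntegrityError(
                    f"{self.slide_id}: tile {t.tile_id} label {t.label!r} differs "
                    f"from its ROI's label {labels[t.roi_id]!r}"
                )


def _encode_vertices(roi: PolygonROI) -> str:
    return ";".join(f"{x:g} {y:g}" for x, y in roi.vertices)


def _decode_vertices(text: str) -> tuple[tuple[float, float], ...]:
    out = []
    for part in text.split(";"):
        x, y = part.split()
        out.append((float(x), float(y)))
    return tuple(out)


def export_dataset(
    pyr: SlidePyramid,
    rois: Sequence[PolygonROI],
    tiles: Sequence[TileSpec],
    out_dir: str | Path,
    image_format: str = "png",
    overwrite: bool = False,
) -> DatasetManifest:
    """Write included tiles and their descriptions under ``out_dir``.

    Creates ``out_dir/<slide_id>/images/tile_%06d.<ext>`` (crops read at
    each tile's own level) and ``out_dir/<slide_id>/descriptions/``
    with ``rois.csv``, ``tiles.csv`` and ``manifest.json``.  Numbering
    starts at 0 in tile order.  A pre-existing slide directory is refused
    unless ``overwrite`` is set, protecting an earlier annotation from
    accidental duplication.
    """
    image_format = image_format.lower()
    if image_format not in ("png", "jpeg"):
        raise ValueError(f"image_format must be 'png' or 'jpeg', got {image_format!r}")
    ext = {"png": "png", "jpeg": "jpg"}[image_format]
    slide_dir = Path(out_dir) / pyr.slide_id
    if slide_dir.exists():
        if not overwrite:
            raise FileExistsError(
                f"{slide_dir} already exists; pass overwrite=True to replace it"
            )
        shutil.rmtree(slide_dir)
    images_dir = slide_dir / "images"
    desc_dir = slide_dir / "descriptions"
    images_dir.mkdir(parents=True)
    desc_dir.mkdir(parents=True)

    label_of = {r.roi_id: r.label for r in rois}
    records: list[TileRecord] = []
    for i, t in enumerate(tiles):
        if t.included is False:
            raise ValueError(f"tile {t.tile_id} is excluded; export included tiles only")
        if t.roi_id not in label_of:
            raise IntegrityError(f"tile {t.tile_id} references unknown ROI {t.roi_id}")
        name = f"tile_{i:06d}.{ext}"
        img = read_region(pyr, t.level, t.origin_l0, (t.side_px, t.side_px))
        pil = Image.fromarray(img.pixels)
        if image_format == "jpeg":
            pil.save(images_dir / name, quality=JPEG_QUALITY)
        else:
            pil.save(images_dir / name)
        records.append(
            TileRecord(
                tile_id=t.tile_id,
                roi_id=t.roi_id,
                label=label_of[t.roi_id],
                level=t.level,
                origin_l0=t.origin_l0,
                side_px=t.side_px,
                overlap_fraction=round(t.overlap_fraction, 6),
                cellularity=None if t.cellularity is None else round(t.cellularity, 6),
                filename=name,
            )
        )

    with open(desc_dir / "rois.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ROIS_HEADER)
        for r in rois:
            bx, by, bw, bh = r.bbox
            w.writerow(
                [r.roi_id, r.label, len(r.vertices), _encode_vertices(r), bx, by, bw, bh]
            )
    with open(desc_dir / "tiles.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TILES_HEADER)
        for rec in records:
            w.writerow(
                [
                    rec.tile_id,
                    rec.roi_id,
                    rec.label,
                    rec.level,
                    rec.origin_l0[0],
                    rec.origin_l0[1],
                    rec.side_px,
                    f"{rec.overlap_fraction:.6f}",
                    "" if rec.cellularity is None else f"{rec.cellularity:.6f}",
                    rec.filename,
                ]
            )
    manifest = DatasetManifest(
        slide_id=pyr.slide_id,
        rois=list(rois),
        tile_records=records,
        image_format=image_format,
    )
    with open(desc_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_manifest_to_json(manifest), fh, indent=1)
    return manifest


def _manifest_to_json(m: DatasetManifest) -> dict:
    return {
        "slide_id": m.slide_id,
        "image_format": m.image_format,
        "rois": [
            {"roi_id": r.roi_id, "label": r.label, "vertices": list(r.vertices)}
            for r in m.rois
        ],
        "tiles": [
            {
                "tile_id": t.tile_id,
                "roi_id": t.roi_id,
                "label": t.label,
                "level": t.level,
                "origin": list(t.origin_l0),
                "side_px": t.side_px,
                "overlap_fraction": t.overlap_fraction,
                "cellularity": t.cellularity,
                "filename": t.filename,
            }
            for t in m.tile_records
        ],
    }


def _read_csv(path: Path, expected_header: list[str]) -> list[dict]:
    if not path.exists():
        raise ManifestParseError(f"missing descriptions file: {path}")
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestParseError(f"{path}: empty file") from None
        if header != expected_header:
            raise ManifestParseError(
                f"{path}, line 1: expected header {expected_header}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise ManifestParseError(
                    f"{path}, line {lineno}: expected {len(expected_header)} fields, "
                    f"got {len(row)}"
                )
            rows.append({"_line": lineno, **dict(zip(expected_header, row))})
    return rows


def load_dataset(out_dir: str | Path, slide_id: str) -> DatasetManifest:
    """Reconstruct a :class:`DatasetManifest` from the descriptions CSVs.

    ``load_dataset`` after :func:`export_dataset` is the identity on
    manifests.  A tile row referencing an unknown ROI raises
    :class:`~histotile.errors.IntegrityError`; malformed CSVs raise
    :class:`~histotile.errors.ManifestParseError` naming file and line.
    """
    desc_dir = Path(out_dir) / slide_id / "descriptions"
    roi_rows = _read_csv(desc_dir / "rois.csv", ROIS_HEADER)
    tile_rows = _read_csv(desc_dir / "tiles.csv", TILES_HEADER)

    rois = []
    for row in roi_rows:
        try:
            rois.append(
                PolygonROI(
                    roi_id=int(row["roi_id"]),
                    vertices=_decode_vertices(row["vertices"]),
                    label=row["label"],
                )
            )
        except (ValueError, KeyError) as exc:
            raise ManifestParseError(
                f"{desc_dir / 'rois.csv'}, line {row['_line']}: {exc}"
            ) from exc

    roi_ids = {r.roi_id for r in rois}
    records = []
    fmt = None
    for row in tile_rows:
        try:
            rid = int(row["roi_id"])
            rec = TileRecord(
                tile_id=int(row["tile_id"]),
                roi_id=rid,
                label=row["label"],
                level=int(row["level"]),
                origin_l0=(int(row["origin_x"]), int(row["origin_y"])),
                side_px=int(row["side_px"]),
                overlap_fraction=float(row["overlap_fraction"]),
                cellularity=float(row["cellularity"]) if row["cellularity"] else None,
                filename=row["filename"],
            )
        except (ValueError, KeyError) as exc:
            raise ManifestParseError(
                f"{desc_dir / 'tiles.csv'}, line {row['_line']}: {exc}"
            ) from exc
        if rid not in roi_ids:
            raise IntegrityError(
                f"{desc_dir / 'tiles.csv'}, line {row['_line']}: tile {rec.tile_id} "
                f"references unknown roi_id {rid}"
            )
        fmt = "jpeg" if rec.filename.endswith(".jpg") else "png"
        records.append(rec)
    if fmt is None:
        manifest_json = desc_dir / "manifest.json"
        if manifest_json.exists():
            fmt = json.loads(manifest_json.read_text())["image_format"]
        else:
            fmt = "png"
    return DatasetManifest(
        slide_id=slide_id, rois=rois, tile_records=records, image_format=fmt
    )


@dataclass(frozen=True)
class SplitAssignment:
    """A patient-level train/val/test partition of slides."""

    assignment: dict[str, str]  # slide_id -> "train" | "val" | "test"
    fractions: tuple[float, float, float]
    seed: int

    def slides(self, split: str) -> list[str]:
        return [s for s, sp in self.assignment.items() if sp == split]


def split_by_patient(
    slide_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly partition slides (= patients) into train/val/test.

    Slides are shuffled by a seeded RNG and cut at ``round(n*f_train)``
    and ``round(n*f_val)``; the remainder is the test set.  All tiles of a
    slide inherit its split, so no patient's tiles leak across sets.
    Deterministic for a fixed seed.
    """
    if len(slide_ids) < 3:
        raise ValueError(f"need at least 3 slides to split, got {len(slide_ids)}")
    if len(set(slide_ids)) != len(slide_ids):
        raise ValueError("slide_ids must be unique")
    f = tuple(float(v) for v in fractions)
    if len(f) != 3 or any(v < 0 for v in f):
        raise ValueError(f"fractions must be 3 non-negative values, got {fractions}")
    if abs(sum(f) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(f)}")
    rng = np.random.default_rng(seed)
    order = list(slide_ids)
    rng.shuffle(order)
    n = len(order)
    n_train = round(n * f[0])
    n_val = round(n * f[1])
    assignment = {}
    for i, sid in enumerate(order):
        assignment[sid] = "train" if i < n_train else "val" if i < n_train + n_val else "test"
    return SplitAssignment(assignment=assignment, fractions=f, seed=seed)


def subsample_per_class(
    tile_records: Sequence[TileRecord],
    n_per_class: int,
    seed: int = 0,
) -> list[TileRecord]:
    """Uniformly sample at most ``n_per_class`` tiles per label.

    Sampling is without replacement with a seeded RNG; classes smaller
    than ``n_per_class`` are kept whole.  Output preserves the original
    record order.  Used to cut within-slide correlation in large tile sets.
    """
    if n_per_class < 0:
        raise ValueError(f"n_per_class must be >= 0, got {n_per_class}")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {}
    for i, rec in enumerate(tile_records):
        by_label.setdefault(rec.label, []).append(i)
    chosen: set[int] = set()
    for label in sorted(by_label):
        idx = by_label[label]
        take = min(n_per_class, len(idx))
        picked = rng.choice(len(idx), size=take, replace=False)
        chosen.update(idx[int(p)] for p in picked)
    return [rec for i, rec in enumerate(tile_records) if i in chosen]
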