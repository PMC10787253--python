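"""Dataset export/recovery layout, patient-level splits, subsampling."""

import numpy as np
import pytest
from PIL import Image

from histotile import (
    InclusionRule,
    TileRecord,
    create_roi,
    export_dataset,
    generate_candidate_tiles,
    load_dataset,
    read_region,
    select_tiles,
    split_by_patient,
    subsample_per_class,
)
from histotile.errors import IntegrityError, ManifestParseError


@pytest.fixture(scope="module")
def annotation(small_pyramid):
    rois = [
        create_roi([(0, 0), (256, 0), (256, 256), (0, 256)], "BRCA", 0),
        create_roi([(256, 256), (512, 256), (512, 512), (256, 512)], "GBM", 1),
    ]
    tiles = []
    next_id = 0
    for roi in rois:
        cands = generate_candidate_tiles(roi, 128, 0, small_pyramid, start_tile_id=next_id)
        next_id += len(cands)
        tiles += [t for t in select_tiles(cands, InclusionRule("min_overlap", 1.0)) if t.included]
    return rois, tiles


class TestExport:
    def test_png_layout_and_naming(self, small_pyramid, annotation, tmp_path):
        rois, tiles = annotation
        manifest = export_dataset(small_pyramid, rois, tiles, tmp_path, "png")
        slide_dir = tmp_path / small_pyramid.slide_id
        names = sorted(p.name for p in (slide_dir / "images").iterdir())
        assert names == [f"tile_{i:06d}.png" for i in range(len(tiles))]
        assert (slide_dir / "descriptions" / "rois.csv").exists()
        assert (slide_dir / "descriptions" / "tiles.csv").exists()
        assert (slide_dir / "descriptions" / "manifest.json").exists()
        assert [t.filename for t in manifest.tile_records] == names

    def test_png_crops_bit_identical_to_read_region(self, small_pyramid, annotation, tmp_path):
        rois, tiles = annotation
        export_dataset(small_pyramid, rois, tiles, tmp_path, "png")
        img_dir = tmp_path / small_pyramid.slide_id / "images"
        for i, t in enumerate(tiles):
            on_disk = np.asarray(Image.open(img_dir / f"tile_{i:06d}.png"))
            direct = read_region(small_pyramid, t.level, t.origin_l0, (t.side_px, t.side_px))
            assert on_disk.shape == (t.side_px, t.side_px, 3)
            np.testing.assert_array_equal(on_disk, direct.pixels)

    def test_empty_tile_list_writes_headers_only(self, small_pyramid, annotation, tmp_path):
        rois, _ = annotation
        manifest = export_dataset(small_pyramid, rois, [], tmp_path, "png")
        assert manifest.tile_records == []
        tiles_csv = tmp_path / small_pyramid.slide_id / "descriptions" / "tiles.csv"
        assert len(tiles_csv.read_text().strip().splitlines()) == 1

    def test_second_export_refused_without_overwrite(self, small_pyramid, annotation, tmp_path):
        rois, tiles = annotation
        export_dataset(small_pyramid, rois, tiles, tmp_path, "png")
        with pytest.raises(FileExistsError):
            export_dataset(small_pyramid, rois, tiles, tmp_path, "png")
        export_dataset(small_pyramid, rois, tiles, tmp_path, "png", overwrite=True)

    def test_unsupported_format_rejected(self, small_pyramid, annotation, tmp_path):
        rois, tiles = annotation
        with pytest.raises(ValueError, match="image_format"):
            export_dataset(small_pyramid, rois, tiles, tmp_path, "webp")


class TestLoadRoundTrip:
    @pytest.mark.parametrize("fmt", ["png", "jpeg"])
    def test_load_after_export_is_identity(self, small_pyramid, annotation, tmp_path, fmt):
        rois, tiles = annotation
        out = tmp_path / fmt
        exported = export_dataset(small_pyramid, rois, tiles, out, fmt)
        loaded = load_dataset(out, small_pyramid.slide_id)
        assert loaded.slide_id == exported.slide_id
        assert loaded.image_format == fmt
        assert [r.vertices for r in loaded.rois] == [r.vertices for r in exported.rois]
        assert [r.label for r in loaded.rois] == [r.label for r in exported.rois]
        assert loaded.tile_records == exported.tile_records

    def test_unknown_roi_reference_is_integrity_error(self, small_pyramid, annotation, tmp_path):
        rois, tiles = annotation
        export_dataset(small_pyramid, rois, tiles, tmp_path, "png")
        tiles_csv = tmp_path / small_pyramid.slide_id / "descriptions" / "tiles.csv"
        lines = tiles_csv.read_text().splitlines()
        lines[1] = lines[1].replace(",0,BRCA,", ",99,BRCA,")
        tiles_csv.write_text("\n".join(lines) + "\n")
        with pytest.raises(IntegrityError, match="roi_id 99"):
            load_dataset(tmp_path, small_pyramid.slide_id)

    def test_corrupt_csv_names_file_and_line(self, small_pyramid, annotation, tmp_path):
        rois, tiles = annotation
        export_dataset(small_pyramid, rois, tiles, tmp_path, "png")
        tiles_csv = tmp_path / small_pyramid.slide_id / "descriptions" / "tiles.csv"
        lines = tiles_csv.read_text().splitlines()
        lines[2] = "garbage,row"
        tiles_csv.write_text("\n".join(lines) + "\n")
        with pytest.raises(ManifestParseError, match="line 3"):
            load_dataset(tmp_path, small_pyramid.slide_id)

    def test_missing_descriptions_raise(self, tmp_path):
        with pytest.raises(ManifestParseError, match="rois.csv"):
            load_dataset(tmp_path, "ghost")

    def test_hand_written_minimal_csvs(self, tmp_path):
        """A dataset authored by hand to the documented schema loads fine."""
        desc = tmp_path / "mini" / "descriptions"
        desc.mkdir(parents=True)
        (desc / "rois.csv").write_text(
            "roi_id,label,n_vertices,vertices,bbox_x,bbox_y,bbox_w,bbox_h\n"
            '0,BRCA,4,"0 0;100 0;100 100;0 100",0,0,100,100\n'
        )
        (desc / "tiles.csv").write_text(
            "tile_id,roi_id,label,level,origin_x,origin_y,side_px,"
            "overlap_fraction,cellularity,filename\n"
            "0,0,BRCA,0,0,0,64,1.000000,0.750000,tile_000000.png\n"
        )
        m = load_dataset(tmp_path, "mini")
        assert len(m.rois) == 1 and len(m.tile_records) == 1
        assert m.tile_records[0].cellularity == pytest.approx(0.75)
        assert m.rois[0].vertices == ((0, 0), (100, 0), (100, 100), (0, 100))


class TestSplitByPatient:
    def test_100_slides_split_60_20_20(self):
        ids = [f"s{i:03d}" for i in range(100)]
        sp = split_by_patient(ids, (0.6, 0.2, 0.2), seed=1)
        assert len(sp.slides("train")) == 60
        assert len(sp.slides("val")) == 20
        assert len(sp.slides("test")) == 20

    def test_five_slides_round_to_3_1_1(self):
        sp = split_by_patient(["a", "b", "c", "d", "e"], (0.6, 0.2, 0.2), seed=0)
        assert (
            len(sp.slides("train")),
            len(sp.slides("val")),
            len(sp.slides("test")),
        ) == (3, 1, 1)

    def test_deterministic_and_partitioning(self):
        ids = [f"s{i}" for i in range(37)]
        a = split_by_patient(ids, seed=5)
        b = split_by_patient(ids, seed=5)
        assert a.assignment == b.assignment
        assert set(a.assignment) == set(ids)  # every slide exactly once
        c = split_by_patient(ids, seed=6)
        assert c.assignment != a.assignment

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            split_by_patient(["a", "b", "c"], (0.8, 0.3, -0.1))
        with pytest.raises(ValueError):
            split_by_patient(["a", "b", "c"], (0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            split_by_patient(["a", "b"], (0.6, 0.2, 0.2))


def _records(n_per_label, labels=("A", "B")):
    recs = []
    i = 0
    for lab in labels:
        for _ in range(n_per_label):
            recs.append(
                TileRecord(i, 0, lab, 0, (0, 0), 64, 1.0, None, f"tile_{i:06d}.png")
            )
            i += 1
    return recs


class TestSubsamplePerClass:
    def test_samples_n_per_class(self):
        out = subsample_per_class(_records(10), 4, seed=0)
        by_label = {}
        for r in out:
            by_label[r.label] = by_label.get(r.label, 0) + 1
        assert by_label == {"A": 4, "B": 4}

    def test_small_class_kept_whole(self):
        out = subsample_per_class(_records(3), 10, seed=0)
        assert len(out) == 6

    def test_deterministic_and_order_preserving(self):
        recs = _records(20)
        a = subsample_per_class(recs, 7, seed=3)
        b = subsample_per_class(recs, 7, seed=3)
        assert a == b
        ids = [r.tile_id for r in a]
        assert ids == sorted(ids)  # original order preserved

    def test_n_zero_keeps_nothing(self):
        assert subsample_per_class(_records(5), 0, seed=0) == []
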