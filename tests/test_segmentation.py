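"""Segmentation: thresholding, labeling vs flood fill, boundary tracing, crops."""

import numpy as np
import pytest

from tabletscan import segmentation as seg
from tabletscan import synthetic as syn
from tabletscan.core import SheetImage

from _oracles import flood_fill_label, outer_edge_set, rasterize_truth, same_partition


def _sheet_from(pixels):
    return SheetImage(pixels=pixels.astype(np.uint8), sheet_id="t")


class TestBinarize:
    def test_all_background_empty(self):
        pixels = np.full((40, 60, 3), 37, dtype=np.uint8)
        mask = seg.binarize(_sheet_from(pixels))
        assert mask.shape == (40, 60)
        assert not mask.any()

    def test_foreground_count_matches_truth_areas(self, zero_noise_sheet):
        """On a noise-free sheet the Otsu mask equals an independent
        rasterization of the truth ellipses, pixel for pixel."""
        sheet, truth = zero_noise_sheet
        mask = seg.binarize(sheet)
        oracle = rasterize_truth(truth, (sheet.height, sheet.width))
        assert int(mask.sum()) == int(oracle.sum())
        assert (mask == oracle).all()

    def test_foreground_is_minority_side_either_polarity(self):
        # light tablets on dark background and the inverse
        base = np.full((60, 60, 3), 30, dtype=np.uint8)
        base[10:20, 10:20] = 220
        m1 = seg.binarize(_sheet_from(base))
        inv = 255 - base
        m2 = seg.binarize(_sheet_from(inv))
        assert m1.sum() == m2.sum() == 100
        assert (m1 == m2).all()

    def test_fixed_threshold_requires_value(self, zero_noise_sheet):
        with pytest.raises(ValueError):
            seg.binarize(zero_noise_sheet[0], method="fixed_threshold")
        m = seg.binarize(zero_noise_sheet[0], method="fixed_threshold",
                         threshold=120)
        assert m.any()


class TestLabelComponents:
    def test_solid_square(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        labels = seg.label_components(m)
        assert labels.max() == 1
        assert (labels[m] == 1).all()

    def test_diagonal_connectivity(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert seg.label_components(m, connectivity=8).max() == 1
        assert seg.label_components(m, connectivity=4).max() == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(60):
            m = rng.random((32, 32)) < rng.uniform(0.2, 0.6)
            got = seg.label_components(m, connectivity=connectivity)
            want = flood_fill_label(m, connectivity=connectivity)
            assert same_partition(got, want)

    def test_ids_dense_from_one(self, rng):
        m = rng.random((24, 24)) < 0.3
        labels = seg.label_components(m)
        present = np.unique(labels[labels > 0])
        assert list(present) == list(range(1, labels.max() + 1))


class TestTraceBoundary:
    def test_single_pixel(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert seg.trace_boundary(m).tolist() == [[1, 1]]

    def test_3x3_square_perimeter(self):
        m = np.zeros((5, 5), bool)
        m[1:4, 1:4] = True
        b = seg.trace_boundary(m)
        assert len(b) == 8
        got = set(map(tuple, b.tolist()))
        assert got == {(x, y) for x in (1, 2, 3) for y in (1, 2, 3)} - {(2, 2)}

    def test_closed_walk_8_adjacent(self, rng):
        for _ in range(40):
            m = rng.random((24, 24)) < 0.42
            labels = seg.label_components(m)
            for rid in range(1, labels.max() + 1):
                b = seg.trace_boundary(labels, rid)
                diffs = np.abs(b - np.roll(b, -1, axis=0))
                assert diffs.max() <= 1

    def test_matches_outer_edge_oracle(self, rng):
        for _ in range(40):
            m = rng.random((32, 32)) < 0.42
            labels = seg.label_components(m)
            for rid in range(1, labels.max() + 1):
                got = set(map(tuple, seg.trace_boundary(labels, rid).tolist()))
                assert got == outer_edge_set(labels == rid)

    def test_unknown_region(self):
        m = np.zeros((3, 3), bool)
        m[0, 0] = True
        with pytest.raises(KeyError):
            seg.trace_boundary(seg.label_components(m), 7)


class TestFilterRegions:
    def test_min_area_one_keep_is_identity(self, rng):
        m = rng.random((32, 32)) < 0.3
        regions = seg.extract_regions(seg.label_components(m))
        out = seg.filter_regions(regions, 1, (32, 32), border_policy="keep")
        assert out == regions

    def test_speck_removed_tablets_kept(self, zero_noise_sheet):
        sheet, truth = zero_noise_sheet
        pixels = sheet.pixels.copy()
        pixels[200:201, 250:252] = 240  # 2-px debris speck
        mask = seg.binarize(_sheet_from(pixels))
        regions = seg.extract_regions(seg.label_components(mask))
        kept = seg.filter_regions(regions, 50, (sheet.height, sheet.width))
        assert len(regions) == len(truth) + 1
        assert len(kept) == len(truth)

    def test_border_tablet_dropped_or_kept(self):
        pixels = np.full((60, 80, 3), 30, dtype=np.uint8)
        pixels[0:10, 20:30] = 230  # touches top edge
        pixels[30:40, 40:50] = 230
        mask = seg.binarize(_sheet_from(pixels))
        regions = seg.extract_regions(seg.label_components(mask))
        assert len(seg.filter_regions(regions, 1, (60, 80), "drop")) == 1
        assert len(seg.filter_regions(regions, 1, (60, 80), "keep")) == 2

    def test_min_area_validation(self):
        with pytest.raises(ValueError):
            seg.filter_regions([], 0, (4, 4))


class TestCropTablets:
    def test_crop_dims_equal_bbox(self, zero_noise_sheet):
        sheet, _ = zero_noise_sheet
        regions, crops, _ = seg.segment_sheet(sheet,
                                              min_area=seg.default_min_area(14))
        for r, c in zip(regions, crops):
            x0, y0, x1, y1 = r.bbox
            assert c.pixels.shape == (y1 - y0 + 1, x1 - x0 + 1, 3)

    def test_each_crop_contains_one_truth_centroid(self, zero_noise_sheet):
        sheet, truth = zero_noise_sheet
        _, crops, _ = seg.segment_sheet(sheet, min_area=seg.default_min_area(14))
        assert len(crops) == len(truth)
        for c in crops:
            x0, y0, x1, y1 = c.bbox
            hits = [r for r in truth if x0 <= r.cx <= x1 and y0 <= r.cy <= y1]
            assert len(hits) == 1

    def test_padding_expands_clipped(self, zero_noise_sheet):
        sheet, _ = zero_noise_sheet
        regions, crops0, _ = seg.segment_sheet(sheet, padding=0,
                                               min_area=seg.default_min_area(14))
        _, crops3, _ = seg.segment_sheet(sheet, padding=3,
                                         min_area=seg.default_min_area(14))
        for a, b in zip(crops0, crops3):
            assert b.pixels.shape[0] == a.pixels.shape[0] + 6
            assert b.pixels.shape[1] == a.pixels.shape[1] + 6

    def test_write_read_round_trip(self, tmp_path, labelled_crops):
        import imageio.v3 as iio

        paths = seg.write_crops(labelled_crops[:3], tmp_path)
        for c, p in zip(labelled_crops[:3], paths):
            assert np.array_equal(iio.imread(p), c.pixels)


class TestRegionInvariants:
    def test_partition_disjoint_and_boundary_on_region(self, noisy_sheet):
        sheet, _ = noisy_sheet
        mask = seg.binarize(sheet)
        labels = seg.label_components(mask)
        regions = seg.extract_regions(labels, sheet.sheet_id)
        total = sum(r.pixel_count for r in regions)
        assert total == int(mask.sum())  # pairwise disjoint, exhaustive
        for r in regions:
            for x, y in r.boundary:
                assert labels[y, x] == r.region_id
            x0, y0, x1, y1 = r.bbox
            sub = labels[y0 : y1 + 1, x0 : x1 + 1] == r.region_id
            assert sub.any(axis=0).all() and sub.any(axis=1).all()  # tight bbox

    def test_count_recovery_on_default_sheets(self):
        """Filtered region count equals generated tablet count on seeded
        default-preset sheets."""
        classes = syn.default_classes(2)
        for s in range(10):
            spec = syn.SheetSpec(width_px=320, height_px=240, seed=100 + s)
            sheet, truth = syn.generate_sheet(spec, classes)
            _, crops, _ = seg.segment_sheet(sheet,
                                            min_area=seg.default_min_area(14.7))
            assert len(crops) == len(truth)
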