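"""Background threshold, flood fill, label consolidation and export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdcell import BBox, LabelSet, consolidate_labels, \
    estimate_background_threshold, export_yolo, flood_fill_cell, \
    import_yolo, mask_to_bbox
from crowdcell.boxes import boxes_from_consensus, export_coco
from crowdcell.detection_eval import iou


def disc_image(radius=15, value=0.8, size=64, center=None):
    center = center or (size // 2, size // 2)
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    mask = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2
    img[mask] = value
    return img, mask, center


class TestBackgroundThreshold:
    def test_bimodal_plane_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        plane = np.where(rng.random((100, 100)) < 0.7,
                         rng.normal(0.1, 0.02, (100, 100)),
                         rng.normal(0.8, 0.02, (100, 100)))
        res = estimate_background_threshold(np.clip(plane, 0, 1))
        assert 0.15 < res.threshold < 0.75
        assert not res.fallback

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        plane = np.where(rng.random((100, 100)) < 0.7,
                         rng.normal(0.1, 0.02, (100, 100)),
                         rng.normal(0.6, 0.02, (100, 100)))
        a = estimate_background_threshold(plane)
        b = estimate_background_threshold(plane + 0.2)
        bin_width = np.ptp(plane) / 256
        assert b.threshold - a.threshold == pytest.approx(0.2, abs=bin_width)

    def test_unimodal_noise_takes_fallback(self):
        rng = np.random.default_rng(2)
        plane = rng.normal(0.05, 0.005, (50, 50))
        assert estimate_background_threshold(plane).fallback

    def test_constant_plane_rejected(self):
        with pytest.raises(ValueError):
            estimate_background_threshold(np.full((10, 10), 0.3))


class TestFloodFill:
    def test_uniform_disc_recovered(self):
        img, disc, center = disc_image()
        mask = flood_fill_cell(img, center, background_threshold=0.1,
                               max_radius=30)
        got = np.zeros_like(disc)
        got[mask.pixels[:, 1], mask.pixels[:, 0]] = True
        inter = (got & disc).sum()
        union = (got | disc).sum()
        assert inter / union >= 0.95

    def test_tight_color_tolerance_separates_touching_cells(self):
        size = 80
        yy, xx = np.mgrid[0:size, 0:size]
        disc_a = (xx - 25) ** 2 + (yy - 40) ** 2 <= 15 ** 2
        disc_b = (xx - 55) ** 2 + (yy - 40) ** 2 <= 15 ** 2
        rgb = np.zeros((size, size, 3))
        rgb[disc_a] = (0.8, 0.1, 0.1)
        rgb[disc_b] = (0.1, 0.1, 0.8)
        mask = flood_fill_cell(rgb, (25, 40), color_tolerance=0.3,
                               background_threshold=0.05, max_radius=40)
        got = np.zeros((size, size), dtype=bool)
        got[mask.pixels[:, 1], mask.pixels[:, 0]] = True
        assert not (got & disc_b).any()
        assert (got & disc_a).sum() / disc_a.sum() >= 0.9

    def test_zero_max_radius_gives_seed_only(self):
        img, _, center = disc_image()
        mask = flood_fill_cell(img, center, background_threshold=0.1,
                               max_radius=0)
        assert mask.pixels.tolist() == [list(center)]

    def test_seed_on_background_flagged(self):
        img, _, _ = disc_image()
        mask = flood_fill_cell(img, (1, 1), background_threshold=0.1)
        assert mask.seed_on_background
        assert len(mask.pixels) == 1

    def test_mask_is_4_connected(self):
        img, _, center = disc_image()
        mask = flood_fill_cell(img, center, background_threshold=0.1)
        pix = set(map(tuple, mask.pixels))
        # every pixel other than the seed has a 4-neighbor in the mask
        for x, y in pix:
            if (x, y) == mask.seed:
                continue
            assert any((x + dx, y + dy) in pix
                       for dx, dy in ((0, 1), (0, -1), (1, 0), (-1, 0)))


class TestMaskToBBox:
    def test_single_pixel_box(self):
        from crowdcell.boxes import CellMask
        mask = CellMask(seed=(3, 4), pixels=np.array([[3, 4]]))
        box = mask_to_bbox(mask, "tumor")
        assert (box.x_min, box.x_max, box.y_min, box.y_max) == (3, 4, 4, 5)

    def test_disc_box_side_close_to_diameter(self):
        r = 12
        img, _, center = disc_image(radius=r)
        mask = flood_fill_cell(img, center, background_threshold=0.1,
                               max_radius=40)
        box = mask_to_bbox(mask, "tumor")
        assert abs((box.x_max - box.x_min) - (2 * r + 1)) <= 2
        assert abs((box.y_max - box.y_min) - (2 * r + 1)) <= 2

    def test_union_bbox_contains_individual_bboxes(self):
        from crowdcell.boxes import CellMask
        a = CellMask(seed=(0, 0), pixels=np.array([[0, 0], [1, 0]]))
        b = CellMask(seed=(5, 7), pixels=np.array([[5, 7]]))
        u = CellMask(seed=(0, 0),
                     pixels=np.vstack([a.pixels, b.pixels]))
        ba, bb, bu = (mask_to_bbox(m, "tumor") for m in (a, b, u))
        for inner in (ba, bb):
            assert bu.x_min <= inner.x_min and bu.x_max >= inner.x_max
            assert bu.y_min <= inner.y_min and bu.y_max >= inner.y_max

    def test_consensus_row_order_irrelevant(self):
        img, _, _ = disc_image(radius=10, size=100, center=(30, 30))
        img2, _, _ = disc_image(radius=10, size=100, center=(70, 70))
        plane = img + img2
        cons = pd.DataFrame({"class": "tumor", "x": [30.0, 70.0],
                             "y": [30.0, 70.0], "support": [8, 8],
                             "accepted": True})
        a = boxes_from_consensus(plane, cons, "i", 10)
        b = boxes_from_consensus(plane, cons.iloc[::-1], "i", 10)
        assert sorted(map(str, a.boxes)) == sorted(map(str, b.boxes))


class TestConsolidate:
    def _ls(self, image_id, boxes):
        return LabelSet(image_id=image_id, width=200, height=200,
                        boxes=boxes)

    def test_empty_cross_detector_keeps_labels(self):
        astro = self._ls("a0", [BBox("astrocyte", 0, 0, 10, 10, 0.8)])
        tumor = self._ls("t0", [BBox("tumor", 5, 5, 15, 15, 0.9)])
        out = consolidate_labels([astro], [tumor], lambda ls, cls: [])
        by_id = {ls.image_id: ls.boxes for ls in out}
        assert by_id["a0"] == astro.boxes and by_id["t0"] == tumor.boxes

    def test_oracle_detector_supplies_missing_class(self):
        astro = self._ls("a0", [BBox("astrocyte", 0, 0, 10, 10, 0.8)])
        tumor = self._ls("t0", [BBox("tumor", 50, 50, 60, 60, 0.9)])
        oracle = {("a0", "tumor"): [BBox("tumor", 100, 100, 120, 120, 0.7)],
                  ("t0", "astrocyte"): [BBox("astrocyte", 0, 0, 20, 20, 0.6)]}
        out = consolidate_labels([astro], [tumor],
                                 lambda ls, cls: oracle[(ls.image_id, cls)])
        for ls in out:
            assert {b.cell_class for b in ls.boxes} == {"astrocyte", "tumor"}

    def test_high_iou_overlap_keeps_higher_confidence(self):
        crowd = BBox("tumor", 0, 0, 10, 10, 0.9)
        detector = BBox("tumor", 1, 0, 11, 10, 0.5)  # IoU = 9/11 > 0.5
        tumor = self._ls("t0", [crowd])
        out = consolidate_labels([], [tumor], lambda ls, cls: [detector])
        assert out[0].boxes == [crowd]

    def test_shared_image_pools_rejected(self):
        ls = self._ls("x", [])
        with pytest.raises(ValueError):
            consolidate_labels([ls], [ls], lambda l, c: [])


class TestYoloExport:
    def test_full_image_box(self):
        ls = LabelSet("i", 64, 64, [BBox("astrocyte", 0, 0, 64, 64)])
        assert export_yolo(ls) == "0 0.500000 0.500000 1.000000 1.000000\n"

    def test_normalization_arithmetic(self):
        ls = LabelSet("i", 100, 200, [BBox("tumor", 10, 20, 30, 60)])
        assert export_yolo(ls) == "1 0.200000 0.200000 0.200000 0.200000\n"

    def test_export_import_export_is_byte_identical(self):
        ls = LabelSet("i", 640, 480,
                      [BBox("tumor", 17, 3, 101, 77),
                       BBox("astrocyte", 200.5, 100.25, 300.75, 190.5)])
        text = export_yolo(ls)
        back = import_yolo(text, "i", 640, 480)
        assert export_yolo(back) == text

    def test_box_outside_image_rejected(self):
        ls = LabelSet("i", 50, 50, [BBox("tumor", 40, 40, 60, 60)])
        with pytest.raises(ValueError):
            export_yolo(ls)

    @settings(derandomize=True, max_examples=50)
    @given(x0=st.integers(0, 90), y0=st.integers(0, 90),
           w=st.integers(1, 10), h=st.integers(1, 10))
    def test_round_trip_recovers_box_within_quantization(self, x0, y0, w, h):
        ls = LabelSet("i", 100, 100,
                      [BBox("tumor", x0, y0, x0 + w, y0 + h)])
        back = import_yolo(export_yolo(ls), "i", 100, 100)
        b = back.boxes[0]
        for got, want in ((b.x_min, x0), (b.y_min, y0),
                          (b.x_max, x0 + w), (b.y_max, y0 + h)):
            assert got == pytest.approx(want, abs=1e-3)

    def test_coco_export_structure(self):
        ls = LabelSet("i", 100, 100, [BBox("tumor", 10, 10, 30, 40, 0.5)])
        coco = export_coco([ls])
        assert coco["annotations"][0]["bbox"] == [10, 10, 20, 30]
        assert {c["name"] for c in coco["categories"]} == \
            {"astrocyte", "tumor"}
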