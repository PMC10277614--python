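"""Overview rendering, scale-bar selection, insets and ROI annotation."""

import math
from pathlib import Path

import numpy as np
import pytest

from pathoverview import (
    CalibrationMissingError,
    RegionL0,
    SlidePyramid,
    Transform,
    annotate_roi,
    choose_level,
    compute_scale_bar,
    extract_inset,
    extract_overview,
    read_region,
    resolve_roi,
)
from conftest import oracle_window

NICE = {m * 10.0**k for k in range(-2, 6) for m in (1, 2, 5)}


def _fake_pyramid() -> SlidePyramid:
    return SlidePyramid(
        source_path=Path("fake.tiff"),
        level_count=4,
        level_dims=[(200000, 150000), (50000, 37500), (12500, 9375), (3125, 2344)],
        level_downsamples=[1.0, 4.0, 16.0, 64.0],
        mpp=(0.25, 0.25),
    )


class TestChooseLevel:
    @pytest.mark.parametrize(
        "target,expected_downsample",
        [(2000, 64.0), (10000, 16.0), (200000, 1.0)],
    )
    def test_finest_level_fitting_target(self, target, expected_downsample):
        slide = _fake_pyramid()
        extent = RegionL0(0, 0, 80000, 60000)
        level = choose_level(slide, extent, target)
        assert slide.level_downsamples[level] == expected_downsample

    def test_coarsest_level_when_nothing_fits(self):
        slide = _fake_pyramid()
        level = choose_level(slide, RegionL0(0, 0, 200000, 150000), 64)
        assert level == slide.level_count - 1

    def test_monotone_in_target(self):
        slide = _fake_pyramid()
        extent = RegionL0(0, 0, 80000, 60000)
        downs = [
            slide.level_downsamples[choose_level(slide, extent, t)]
            for t in (100, 500, 2000, 8000, 30000, 100000)
        ]
        assert downs == sorted(downs, reverse=True)


class TestComputeScaleBar:
    @pytest.mark.parametrize(
        "um_per_px,width,expected_um,expected_px,label",
        [
            (4.0, 1250, 1000.0, 250, "1.0 mm"),   # the 1.0 mm overview bar
            (0.25, 1000, 50.0, 200, "50 µm"),
            (1.0, 1000, 200.0, 200, "200 µm"),    # 500 µm would exceed 40%
            (1.25, 1000, 200.0, 160, "200 µm"),   # log-distance tiebreak
        ],
    )
    def test_nice_value_selection(self, um_per_px, width, expected_um,
                                  expected_px, label):
        bar = compute_scale_bar(um_per_px, width)
        assert bar.length_um == expected_um
        assert bar.length_px == expected_px
        assert bar.label == label

    def test_matches_candidate_enumeration(self):
        # oracle: enumerate all nice candidates and minimise log-distance
        for um_per_px in (0.25, 0.5, 1.0, 2.2, 4.0, 7.3):
            for width in (640, 1000, 1250, 2000):
                bar = compute_scale_bar(um_per_px, width)
                width_um = width * um_per_px
                target = 0.25 * width_um
                pool = [c for c in NICE if 0.10 <= c / width_um <= 0.40]
                best = min(pool, key=lambda c: abs(math.log(c / target)))
                assert bar.length_um == best

    def test_physical_truth_and_window(self):
        for um_per_px in (0.22, 0.25, 1.0, 3.7, 4.0, 9.9):
            for width in (320, 640, 1000, 1600):
                bar = compute_scale_bar(um_per_px, width)
                assert bar.length_um in NICE
                assert abs(bar.length_px * um_per_px - bar.length_um) <= um_per_px / 2 + 1e-9
                assert 0.10 <= bar.length_px / width <= 0.40 + 1e-9


class TestExtractOverview:
    def test_target_size_scale_bar_and_downsample(self, ellipse_slide):
        _, truth, slide = ellipse_slide
        ov = extract_overview(slide, truth.tissue_bbox_l0, target_px=1000)
        body = ov.body
        assert max(body.shape[:2]) == 1000
        assert ov.effective_downsample == pytest.approx(
            truth.tissue_bbox_l0.w / body.shape[1], rel=1e-9
        )
        assert ov.scale_bar is not None
        # physical truth on the rendered bar: 5000 l0 px crop at mpp 0.25
        # over 1000 px -> 1.25 um/px -> 200 um bar, 160 px
        assert ov.scale_bar.length_um == 200.0
        assert ov.scale_bar.length_px == 160
        assert ov.margin_band_px > 0

    def test_missing_calibration_suppresses_bar(self, uncalibrated_slide):
        bbox = RegionL0(1500, 1500, 5000, 3000)
        with pytest.warns(UserWarning, match="without a scale bar"):
            ov = extract_overview(uncalibrated_slide, bbox, target_px=500)
        assert ov.scale_bar is None
        assert ov.margin_band_px == 0

    def test_quarter_turn_swaps_axes(self, ellipse_slide):
        _, truth, slide = ellipse_slide
        plain = extract_overview(slide, truth.tissue_bbox_l0, target_px=500,
                                 with_scale_bar=False)
        rot = extract_overview(slide, truth.tissue_bbox_l0, target_px=500,
                               transform=Transform(rotate90=1),
                               with_scale_bar=False)
        assert rot.body.shape[:2] == plain.body.shape[1::-1]
        np.testing.assert_array_equal(rot.body, np.rot90(plain.body))

    def test_no_upsampling_beyond_data(self, ellipse_slide):
        _, _, slide = ellipse_slide
        small = RegionL0(3900, 2900, 200, 200)
        ov = extract_overview(slide, small, target_px=1000, with_scale_bar=False)
        assert max(ov.body.shape[:2]) == 200  # finest data, never fabricated


class TestTransformGroup:
    def test_half_turn_twice_is_identity(self):
        rng = np.random.default_rng(7)
        px = rng.integers(0, 255, (13, 17, 3), dtype=np.uint8)
        t = Transform(rotate90=2)
        np.testing.assert_array_equal(t.apply(t.apply(px)), px)

    def test_flip_twice_is_identity(self):
        rng = np.random.default_rng(8)
        px = rng.integers(0, 255, (13, 17, 3), dtype=np.uint8)
        t = Transform(flip_h=True)
        np.testing.assert_array_equal(t.apply(t.apply(px)), px)

    def test_four_quarter_turns_identity(self):
        rng = np.random.default_rng(9)
        px = rng.integers(0, 255, (10, 20, 3), dtype=np.uint8)
        out = px
        for _ in range(4):
            out = Transform(rotate90=1).apply(out)
        np.testing.assert_array_equal(out, px)

    @pytest.mark.parametrize("rotate90", [0, 1, 2, 3])
    @pytest.mark.parametrize("flip_h", [False, True])
    def test_map_rect_agrees_with_marked_image(self, rotate90, flip_h):
        # oracle: mark the rect in an indicator image, transform the image,
        # and locate the marks
        t = Transform(rotate90=rotate90, flip_h=flip_h)
        w, h = 40, 28
        x, y, rw, rh = 5, 8, 12, 9
        ind = np.zeros((h, w), dtype=bool)
        ind[y : y + rh, x : x + rw] = True
        moved = np.rot90(ind, k=rotate90)
        if flip_h:
            moved = np.fliplr(moved)
        rows = np.flatnonzero(moved.any(axis=1))
        cols = np.flatnonzero(moved.any(axis=0))
        expected = (cols[0], rows[0], cols[-1] + 1 - cols[0], rows[-1] + 1 - rows[0])
        got = t.map_rect(x, y, rw, rh, w, h)
        assert tuple(round(v) for v in got) == expected


class TestInset:
    @pytest.mark.parametrize(
        "width_um,mpp,expected_l0_px", [(250.0, 0.25, 1000), (500.0, 0.25, 2000)]
    )
    def test_physical_width_arithmetic(self, ellipse_slide, width_um, mpp,
                                       expected_l0_px):
        _, _, slide = ellipse_slide
        assert slide.mpp[0] == mpp
        roi = resolve_roi(slide, roi_center=(4000, 3000),
                          physical_width_um=width_um)
        assert roi.w == expected_l0_px
        assert roi.h == expected_l0_px

    def test_checkerboard_inset_matches_oracle(self, ellipse_slide, ellipse_spec):
        # ROI 1000 l0 px wide at out_px 250 reads level d=4 with no resize,
        # so the inset must equal the oracle's level-1 window exactly
        _, truth, slide = ellipse_slide
        roi = truth.roi_region
        inset = extract_inset(slide, roi=roi, out_px=250)
        assert inset.width == 250
        expected = oracle_window(
            ellipse_spec, roi.x // 4, roi.y // 4, 250, 250, 4.0
        )
        np.testing.assert_array_equal(inset.pixels, expected)

    def test_missing_calibration_instructs_pixel_roi(self, uncalibrated_slide):
        with pytest.raises(CalibrationMissingError, match="pixel-unit"):
            extract_inset(
                uncalibrated_slide, roi_center=(100, 100), physical_width_um=250
            )

    def test_pixel_roi_path_needs_no_calibration(self, uncalibrated_slide):
        inset = extract_inset(
            uncalibrated_slide, roi=RegionL0(3500, 2500, 1000, 1000), out_px=250
        )
        assert inset.width == 250

    def test_inset_overview_colour_consistency(self, ellipse_slide):
        _, truth, slide = ellipse_slide
        roi = truth.roi_region
        ov = extract_overview(slide, truth.tissue_bbox_l0, target_px=1000,
                              with_scale_bar=False)
        inset = extract_inset(slide, roi=roi, out_px=200)
        d = ov.effective_downsample
        x0 = round((roi.x - ov.crop.x) / d)
        y0 = round((roi.y - ov.crop.y) / d)
        x1 = round((roi.x + roi.w - ov.crop.x) / d)
        y1 = round((roi.y + roi.h - ov.crop.y) / d)
        ov_mean = ov.body[y0:y1, x0:x1].mean(axis=(0, 1))
        inset_mean = inset.pixels.mean(axis=(0, 1))
        assert np.all(np.abs(ov_mean - inset_mean) <= 5.0)


class TestAnnotateRoi:
    def test_rectangle_position_and_size(self, ellipse_slide):
        _, truth, slide = ellipse_slide
        ov = extract_overview(slide, truth.tissue_bbox_l0, target_px=1000,
                              with_scale_bar=False)
        assert ov.effective_downsample == pytest.approx(5.0)
        roi = RegionL0(3500, 2500, 1000, 1000)
        ann = annotate_roi(ov, roi)
        body = ann.body
        # expected at ((3500-1500)/5, (2500-1500)/5) = (400, 200), 200x200
        assert (body[200:202, 400:600] == 0).all()
        assert (body[398:400, 400:600] == 0).all()
        assert (body[200:400, 400:402] == 0).all()
        assert (body[200:400, 598:600] == 0).all()
        # input untouched
        assert not (ov.body[200:202, 400:600] == 0).all()

    def test_rotated_annotation_matches_rotated_plain_annotation(self, ellipse_slide):
        _, truth, slide = ellipse_slide
        roi = RegionL0(3500, 2500, 1000, 1000)
        plain = annotate_roi(
            extract_overview(slide, truth.tissue_bbox_l0, target_px=800,
                             with_scale_bar=False), roi)
        rot = annotate_roi(
            extract_overview(slide, truth.tissue_bbox_l0, target_px=800,
                             transform=Transform(rotate90=1),
                             with_scale_bar=False), roi)
        np.testing.assert_array_equal(rot.body, np.rot90(plain.body))

    def test_disjoint_roi_is_noop_with_warning(self, ellipse_slide):
        _, truth, slide = ellipse_slide
        ov = extract_overview(slide, truth.tissue_bbox_l0, target_px=500,
                              with_scale_bar=False)
        with pytest.warns(UserWarning, match="does not intersect"):
            ann = annotate_roi(ov, RegionL0(0, 0, 100, 100))
        np.testing.assert_array_equal(ann.image.pixels, ov.image.pixels)
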