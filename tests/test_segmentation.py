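"""Thresholding, particle labelling, measurement and scale calibration."""

import math

import numpy as np
import pytest

from _oracles import flood_fill_components, otsu_oracle
from microcensus import (
    CalibrationError,
    DegenerateImageError,
    ScaleCalibration,
    ValidationError,
    calibrate_scale,
    filter_particles,
    label_particles,
    measure_particles,
    otsu_threshold,
    threshold_residual,
)
from microcensus.census import RegionOfInterest

SCALE10 = ScaleCalibration(10.0)


class TestThreshold:
    def test_fixed_bright_selects_strictly_above(self):
        img = np.zeros((8, 8), np.uint8)
        img[3, 4] = 200
        mask = threshold_residual(img, "fixed", "bright", value=50)
        assert mask.pixels.sum() == 1 and mask.pixels[3, 4]
        assert mask.threshold_used == 50

    def test_all_zero_residual_gives_empty_mask(self):
        mask = threshold_residual(np.zeros((5, 5), np.uint8), "fixed", "bright", value=1)
        assert not mask.pixels.any()

    def test_otsu_two_level_image(self):
        img = np.concatenate([np.full(40, 10), np.full(24, 200)]).astype(np.uint8).reshape(8, 8)
        mask = threshold_residual(img, "otsu", "bright")
        assert 10 < mask.threshold_used < 200
        assert mask.pixels.sum() == 24

    def test_otsu_matches_exhaustive_search(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            assert otsu_threshold(img) == otsu_oracle(img)

    def test_otsu_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 7, np.uint8))

    def test_foreground_monotone_in_fixed_threshold(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        counts = [
            threshold_residual(img, "fixed", "bright", value=t).pixels.sum()
            for t in range(0, 256, 16)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_dark_polarity_selects_below(self):
        img = np.array([[10, 200]], np.uint8)
        mask = threshold_residual(img, "fixed", "dark", value=50)
        assert mask.pixels.tolist() == [[True, False]]


class TestLabelParticles:
    def test_empty_mask_has_zero_particles(self):
        _, count = label_particles(np.zeros((6, 6), bool))
        assert count == 0

    def test_diagonal_contact_depends_on_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_particles(mask, connectivity=8)[1] == 1
        assert label_particles(mask, connectivity=4)[1] == 2

    def test_disjoint_squares_counted(self):
        mask = np.zeros((20, 20), bool)
        for k in range(3):
            mask[6 * k + 1 : 6 * k + 4, 1:4] = True
        assert label_particles(mask)[1] == 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        for _ in range(15):
            mask = rng.random((24, 24)) < 0.35
            _, count = label_particles(mask, connectivity)
            _, expected = flood_fill_components(mask, connectivity)
            assert count == expected

    def test_particle_areas_sum_to_foreground_pixels(self, rng):
        mask = rng.random((32, 32)) < 0.3
        labels, _ = label_particles(mask)
        records = measure_particles(labels, np.zeros((32, 32), np.uint8), SCALE10)
        assert sum(r.area_px for r in records) == int(mask.sum())


class TestMeasureParticles:
    def _single(self, mask, scale=SCALE10, **kw):
        labels, _ = label_particles(mask)
        return measure_particles(labels, np.zeros(mask.shape, np.uint8), scale, **kw)

    def test_filled_square_area_in_mm2(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True  # 10x10 px at 10 px/mm = 1 mm^2
        (rec,) = self._single(mask)
        assert rec.area_mm2 == pytest.approx(1.0)

    def test_single_pixel_particle(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 6] = True
        (rec,) = self._single(mask)
        assert rec.area_mm2 == pytest.approx(1 / 100)
        assert rec.centroid == (4.0, 6.0)
        assert rec.length_mm == pytest.approx(0.1)  # one pixel span

    def test_rectangle_length_matches_moment_formula(self):
        mask = np.zeros((40, 12), bool)
        mask[5:35, 4:8] = True  # 30 rows x 4 cols
        (rec,) = self._single(mask)
        # moment-ellipse major axis of a discrete uniform bar of n pixels:
        # 4 * sqrt((n^2 - 1) / 12)
        expected_px = 4 * math.sqrt((30**2 - 1) / 12)
        assert rec.length_mm == pytest.approx(expected_px / 10, rel=1e-6)
        # orientation along rows: bbox is tall, not wide
        assert rec.bbox == (5, 4, 35, 8)

    def test_translation_invariance(self):
        base = np.zeros((30, 30), bool)
        base[3:9, 4:12] = True
        moved = np.roll(base, (10, 7), axis=(0, 1))
        (a,) = self._single(base)
        (b,) = self._single(moved)
        assert b.centroid == (a.centroid[0] + 10, a.centroid[1] + 7)
        assert b.area_mm2 == a.area_mm2
        assert b.length_mm == pytest.approx(a.length_mm)

    def test_mean_intensity_and_colour_from_source(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = mask[2, 3] = True
        gray = np.zeros((5, 5), np.uint8)
        gray[2, 2], gray[2, 3] = 100, 200
        rgb = np.zeros((5, 5, 3), np.uint8)
        rgb[2, 2] = (10, 20, 30)
        rgb[2, 3] = (30, 40, 50)
        labels, _ = label_particles(mask)
        (rec,) = measure_particles(labels, gray, SCALE10, colour_frame=rgb)
        assert rec.mean_intensity == pytest.approx(150.0)
        assert rec.mean_colour == (20.0, 30.0, 40.0)

    def test_missing_scale_instructs_calibration(self):
        labels, _ = label_particles(np.ones((3, 3), bool))
        with pytest.raises(ValidationError, match="calibrat"):
            measure_particles(labels, np.zeros((3, 3), np.uint8), None)


class TestFilterParticles:
    def _records(self, areas):
        mask = np.zeros((50, 50), bool)
        # distinct squares whose areas map to the requested mm^2 at 10 px/mm
        recs = []
        for i, a in enumerate(areas):
            side = int(round(math.sqrt(a * 100)))
            m = np.zeros((50, 50), bool)
            m[1 : 1 + side, 1 : 1 + side] = True
            labels, _ = label_particles(m)
            recs.extend(measure_particles(labels, np.zeros((50, 50), np.uint8), SCALE10))
        return recs

    def test_wide_open_bounds_keep_everything(self):
        recs = self._records([0.5, 1.5])
        assert filter_particles(recs) == recs

    def test_area_gate(self):
        recs = self._records([0.49, 1.44, 3.24])
        kept = filter_particles(recs, min_area_mm2=1.0, max_area_mm2=2.0)
        assert [r.area_mm2 for r in kept] == pytest.approx([1.44])

    def test_roi_membership_by_centroid(self):
        recs = self._records([1.0])
        roi_far = RegionOfInterest.rectangle(30, 30, 49, 49)
        assert filter_particles(recs, roi=roi_far) == []
        roi_near = RegionOfInterest.rectangle(0, 0, 20, 20)
        assert len(filter_particles(recs, roi=roi_near)) == 1

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            filter_particles([], min_area_mm2=2.0, max_area_mm2=1.0)

    def test_edge_particles_dropped_on_request(self):
        mask = np.zeros((10, 10), bool)
        mask[0:3, 0:3] = True  # touches the border
        mask[5:8, 5:8] = True
        labels, _ = label_particles(mask)
        recs = measure_particles(labels, np.zeros((10, 10), np.uint8), SCALE10)
        kept = filter_particles(recs, exclude_edge=True, frame_shape=(10, 10))
        assert len(kept) == 1 and kept[0].bbox == (5, 5, 8, 8)


class TestCalibrateScale:
    def test_black_square_of_known_side(self):
        img = np.full((100, 100), 230, np.uint8)
        img[20:70, 30:80] = 5  # 50x50 px
        cal = calibrate_scale(img, reference_side_mm=5.0)
        assert cal.pixels_per_mm == pytest.approx(10.0)
        assert cal.source == "reference_square"

    def test_uniform_image_fails(self):
        with pytest.raises(CalibrationError):
            calibrate_scale(np.full((50, 50), 255, np.uint8), 5.0)

    def test_near_square_blob(self):
        img = np.full((100, 100), 230, np.uint8)
        img[10:50, 10:51] = 5  # 40x41 px = 1640 px^2
        cal = calibrate_scale(img, reference_side_mm=4.0)
        assert cal.pixels_per_mm == pytest.approx(math.sqrt(1640) / 4, rel=1e-6)

    def test_elongated_blob_rejected(self):
        img = np.full((100, 100), 230, np.uint8)
        img[10:20, 10:60] = 5  # aspect ratio 0.2
        with pytest.raises(CalibrationError, match="square"):
            calibrate_scale(img, 4.0)
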