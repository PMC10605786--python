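"""Empty-band quantification: binarization, area-fraction grid, detection."""

import numpy as np
import pytest

from cerebromech.fibergap import (
    GRID,
    AmbiguousBandError,
    AreaFractionProfile,
    ConstantImageError,
    FiberGapError,
    LayerAnnotation,
    area_fraction_profile,
    binarize,
    detect_band,
    measure_gap,
    measure_sample,
    media_threshold,
)
from cerebromech import synthetic


def make_profile(fractions, column_width_px=10, roi=(0, 300, 0, 300)):
    fr = np.asarray(fractions, dtype=float)
    assert fr.size == GRID
    return AreaFractionProfile(
        column_fractions=fr,
        cell_fractions=np.tile(fr, (GRID, 1)),
        column_width_px=column_width_px,
        pixel_size_um=1.0,
        roi=roi,
    )


ANNOT = LayerAnnotation(intima=(0, 20), media=(20, 150), adventitia=(180, 300))


def interface_profile():
    """Media ~0.3 (cols 2-14), gap 0.06/0.04/0.07 (cols 15-17), adventitia ~0.5."""
    fr = np.empty(GRID)
    fr[:2] = 0.35
    fr[2:15] = [0.31, 0.29, 0.33, 0.30, 0.32, 0.28, 0.31, 0.33, 0.30, 0.29, 0.32, 0.31, 0.30]
    fr[15:18] = [0.06, 0.04, 0.07]
    fr[18:] = np.linspace(0.46, 0.50, 12)
    return make_profile(fr)


class TestBinarize:
    def test_two_level_image_exact_separation(self):
        img = np.full((50, 50), 10.0)
        img[10:20, 10:40] = 200.0
        assert np.array_equal(binarize(img), img > 100)

    def test_constant_image_errors(self):
        with pytest.raises(ConstantImageError):
            binarize(np.full((30, 30), 42.0))

    def test_generator_mask_recovered(self, fiber_scene):
        binary = binarize(fiber_scene.image.raster)
        agreement = np.mean(binary == fiber_scene.mask)
        assert agreement >= 0.99

    def test_manual_threshold_override(self):
        img = np.full((40, 40), 10.0)
        img[0, 0] = 200.0
        assert binarize(img, threshold=100.0).sum() == 1


class TestAreaFractionProfile:
    def test_all_foreground_gives_unit_columns(self):
        p = area_fraction_profile(np.ones((60, 60), bool), (0, 60, 0, 60))
        assert np.allclose(p.column_fractions, 1.0)

    def test_half_split_300px_roi(self):
        img = np.zeros((300, 300), bool)
        img[:, :150] = True
        p = area_fraction_profile(img, (0, 300, 0, 300))
        assert np.allclose(p.column_fractions[:15], 1.0)
        assert np.allclose(p.column_fractions[15:], 0.0)

    def test_remainder_pixels_counted_in_last_cell(self):
        # 35x35 ROI: cells are 1 px with a 6-px remainder strip on the last
        img = np.ones((40, 40), bool)
        p = area_fraction_profile(img, (0, 35, 0, 35))
        assert np.allclose(p.cell_fractions, 1.0)
        assert p.column_width_px == 1

    def test_roi_outside_image_errors(self):
        with pytest.raises(FiberGapError):
            area_fraction_profile(np.ones((50, 50), bool), (0, 60, 0, 50))

    def test_generator_media_fraction_target(self, fiber_scene):
        binary = binarize(fiber_scene.image.raster)
        p = area_fraction_profile(binary, fiber_scene.roi)
        from cerebromech.fibergap import _grid_columns

        lo, hi = _grid_columns(p, fiber_scene.annotation.media)
        # interior media columns (edges straddle neighbouring layers)
        media_mean = p.column_fractions[lo + 1 : hi - 1].mean()
        assert media_mean == pytest.approx(0.318, abs=0.03)


class TestMediaThreshold:
    def test_pooled_study_statistics(self):
        p = interface_profile()
        tau = media_threshold(p, ANNOT, mode="pooled", pooled_mu=0.318, pooled_sd=0.085)
        assert tau == pytest.approx(0.148, abs=1e-12)

    def test_zero_spread_threshold_is_mean(self):
        fr = np.full(GRID, 0.4)
        tau = media_threshold(make_profile(fr), ANNOT)
        assert tau == pytest.approx(0.4)

    def test_two_column_hand_computation(self):
        ann = LayerAnnotation(intima=(0, 20), media=(20, 40), adventitia=(180, 300))
        fr = np.full(GRID, 0.45)
        fr[2], fr[3] = 0.3, 0.5  # media maps to exactly grid columns 2-3
        tau = media_threshold(make_profile(fr), ann)
        assert tau == pytest.approx(0.4 - 2 * np.std([0.3, 0.5], ddof=1), rel=1e-12)

    def test_single_media_column_rejected(self):
        ann = LayerAnnotation(intima=(0, 10), media=(10, 20), adventitia=(180, 300))
        with pytest.raises(FiberGapError):
            media_threshold(interface_profile(), ann)


class TestDetectBand:
    def test_constructed_three_column_band(self):
        gap = detect_band(interface_profile(), 0.148, ANNOT)
        assert gap.band_columns == (15, 18)
        assert gap.width_um == pytest.approx(30.0)

    def test_no_subthreshold_columns_means_zero_width(self):
        gap = detect_band(interface_profile(), 0.02, ANNOT)
        assert gap.band_columns is None
        assert gap.width_um == 0.0

    def test_multiple_candidate_runs_raise(self):
        fr = interface_profile().column_fractions.copy()
        fr[16] = 0.30  # split the band into two runs at the interface
        with pytest.raises(AmbiguousBandError):
            detect_band(make_profile(fr), 0.148, ANNOT)

    def test_isolated_media_interior_dip_is_not_the_band(self):
        fr = interface_profile().column_fractions.copy()
        fr[4] = 0.05  # sub-threshold column deep inside the media
        gap = detect_band(make_profile(fr), 0.148, ANNOT)
        assert gap.band_columns == (15, 18)

    def test_tau_out_of_range_rejected(self):
        with pytest.raises(FiberGapError):
            detect_band(interface_profile(), 1.5, ANNOT)


class TestEndToEnd:
    def test_gap_recovery_within_one_column(self, fiber_scene):
        gap, profile = measure_gap(fiber_scene.image, fiber_scene.roi)
        assert abs(gap.width_um - fiber_scene.true_gap_um) <= profile.column_width_um

    def test_intensity_scale_invariance(self, fiber_scene):
        from cerebromech.fibergap import FiberImage

        gap1, _ = measure_gap(fiber_scene.image, fiber_scene.roi)
        scaled = FiberImage(
            raster=fiber_scene.image.raster * 2.5,
            pixel_size_um=fiber_scene.image.pixel_size_um,
            annotation=fiber_scene.annotation,
        )
        gap2, _ = measure_gap(scaled, fiber_scene.roi)
        assert gap1.width_um == gap2.width_um

    def test_filled_gap_detected_as_zero(self):
        params = synthetic.FiberSceneParams(
            gap_width_um=32.0, gap_fraction=0.318, noise_sd=0.0
        )
        scene = synthetic.generate_fiber_image(params, seed=3)
        gap, _ = measure_gap(scene.image, scene.roi)
        assert gap.width_um == 0.0


class TestMeasureSample:
    def test_equal_widths(self):
        assert measure_sample([30.0, 30.0, 30.0, 30.0]) == (30.0, 0.0)

    def test_hand_computed_sd(self):
        mean, sd = measure_sample([20.0, 25.0, 35.0, 40.0])
        assert mean == pytest.approx(30.0)
        assert sd == pytest.approx(9.128709, rel=1e-6)

    def test_single_location_sd_missing(self):
        mean, sd = measure_sample([21.0])
        assert mean == 21.0 and sd is None
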