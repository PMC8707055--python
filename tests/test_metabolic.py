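"""Metabolic trajectory projection, f/b ratios, rim masks, age summaries."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from organoidphasor import (
    PhasorField,
    apply_calibration,
    center_of_mass,
    colorize_metabolic,
    decay_to_phasor,
    derive_calibration,
    fb_ratio,
    make_nadh_axis,
    outer_rim_mask,
    project_fb_ratio,
    project_to_axis,
    summarize_age_series,
    universal_circle_point,
)
from conftest import OMEGA


@pytest.fixture(scope="module")
def axis():
    return make_nadh_axis(OMEGA)


def field_at(points, intensity=None, calibrated=True):
    """Tiny calibrated PhasorField from a list of (g, s) pairs."""
    pts = np.asarray(points, dtype=float)
    g = pts[:, 0].reshape(1, -1)
    s = pts[:, 1].reshape(1, -1)
    inten = np.ones_like(g) if intensity is None else np.asarray(intensity, float).reshape(1, -1)
    return PhasorField(g=g, s=s, intensity=inten, omega=OMEGA, calibrated=calibrated)


class TestAxis:
    def test_endpoints_match_closed_form(self, axis):
        assert axis.p_free == pytest.approx(universal_circle_point(0.4, OMEGA), abs=1e-12)
        assert axis.p_bound == pytest.approx(universal_circle_point(3.4, OMEGA), abs=1e-12)

    def test_endpoints_on_universal_circle(self, axis):
        for g, s in (axis.p_free, axis.p_bound):
            assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-12)

    def test_degenerate_lifetimes_rejected(self):
        with pytest.raises(ValueError):
            make_nadh_axis(OMEGA, tau_free=3.4, tau_bound=3.4)
        with pytest.raises(ValueError):
            make_nadh_axis(OMEGA, tau_free=3.4, tau_bound=0.4)


class TestProjection:
    def test_endpoints_and_midpoint(self, axis):
        mid = 0.5 * (np.asarray(axis.p_free) + np.asarray(axis.p_bound))
        f = field_at([axis.p_free, axis.p_bound, tuple(mid)])
        mmap = project_to_axis(f, axis)
        assert mmap.f1[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert mmap.f1[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert mmap.f1[0, 2] == pytest.approx(0.5, abs=1e-12)
        assert fb_ratio(mmap.f1[0, 2]) == pytest.approx(1.0)

    def test_f1_plus_f2_is_one(self, axis):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.1, 0.6, size=(20, 2))
        mmap = project_to_axis(field_at(pts), axis)
        np.testing.assert_array_equal(mmap.f1 + mmap.f2, np.ones_like(mmap.f1))

    def test_out_of_segment_projection_clamped_and_recorded(self, axis):
        beyond_free = (1.05, 0.25)  # past the free endpoint
        mmap = project_to_axis(field_at([beyond_free, axis.p_bound]), axis)
        assert mmap.f1[0, 0] == 1.0
        assert mmap.clamped_mask[0, 0]
        assert not mmap.clamped_mask[0, 1]

    def test_order_preserved_along_chord(self, axis):
        """Pixels closer to the free endpoint never get lower F1."""
        pf, pb = np.asarray(axis.p_free), np.asarray(axis.p_bound)
        ts = np.linspace(0, 1, 11)
        pts = pb + ts[:, None] * (pf - pb)
        mmap = project_to_axis(field_at(pts), axis)
        assert np.all(np.diff(mmap.f1.ravel()) > 0)
        np.testing.assert_allclose(mmap.f1.ravel(), ts, atol=1e-12)

    def test_uncalibrated_field_rejected(self, axis):
        f = field_at([axis.p_free], calibrated=False)
        with pytest.raises(ValueError, match="calibrat"):
            project_to_axis(f, axis)

    def test_omega_mismatch_rejected(self, axis):
        f = replace(field_at([axis.p_free]), omega=2 * OMEGA)
        with pytest.raises(ValueError, match="omega"):
            project_to_axis(f, axis)

    def test_phantom_recovery_noiseless(self, phantom, noiseless_cube, reference_field, axis):
        """Median rim/core F1 recovers the generator's programmed
        intensity fractions (0.7 / 0.3) within 0.02."""
        cal = derive_calibration(reference_field, 2.5)
        f = apply_calibration(decay_to_phasor(noiseless_cube), cal)
        mmap = project_to_axis(f, axis)
        rim = np.nanmedian(mmap.f1[phantom.label_image == 1])
        core = np.nanmedian(mmap.f1[phantom.label_image == 2])
        assert rim == pytest.approx(0.7, abs=0.02)
        assert core == pytest.approx(0.3, abs=0.02)


class TestCenterOfMass:
    def test_single_pixel_mask(self, axis):
        f = field_at([(0.3, 0.2), (0.5, 0.4)])
        mask = np.array([[True, False]])
        assert center_of_mass(f, mask) == pytest.approx((0.3, 0.2))

    def test_equal_intensity_midpoint(self):
        f = field_at([(0.2, 0.1), (0.4, 0.3)])
        assert center_of_mass(f) == pytest.approx((0.3, 0.2))

    def test_intensity_weighting(self):
        f = field_at([(0.0, 0.0), (1.0, 1.0)], intensity=[1.0, 3.0])
        assert center_of_mass(f) == pytest.approx((0.75, 0.75))

    def test_uniform_field_mask_independent(self):
        f = field_at([(0.3, 0.2)] * 5)
        for mask in (None, np.array([[True, False, True, False, True]])):
            assert center_of_mass(f, mask) == pytest.approx((0.3, 0.2))

    def test_empty_mask_rejected(self, axis):
        f = field_at([(0.3, 0.2)])
        with pytest.raises(ValueError):
            center_of_mass(f, np.array([[False]]))


class TestFbRatio:
    @pytest.mark.parametrize("f1, expected", [(0.5, 1.0), (0.0, 0.0), (0.75, 3.0)])
    def test_algebra(self, f1, expected):
        assert fb_ratio(f1) == pytest.approx(expected)

    def test_saturated_fraction_reported_undefined(self):
        assert np.isnan(fb_ratio(1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fb_ratio(1.2)

    def test_scalar_route_uses_center_of_mass(self, axis):
        """The ROI f/b ratio comes from the center-of-mass projection, not
        from averaging per-pixel ratios (they differ off the chord)."""
        pf, pb = np.asarray(axis.p_free), np.asarray(axis.p_bound)
        pts = [pb + 0.2 * (pf - pb), pb + 0.8 * (pf - pb)]
        f = field_at(pts)
        ratio = project_fb_ratio(f, axis)
        assert ratio == pytest.approx(1.0)  # center of mass at F1=0.5
        pixel_mean = np.mean([fb_ratio(0.2), fb_ratio(0.8)])
        assert ratio != pytest.approx(pixel_mean)


class TestColorize:
    def test_constant_field_constant_color(self, axis):
        f = field_at([(0.4, 0.3)] * 4)
        mmap = project_to_axis(f, axis)
        rgb, strip = colorize_metabolic(mmap)
        assert rgb.shape == (*mmap.f1.shape, 3)
        assert len(np.unique(rgb.reshape(-1, 3), axis=0)) == 1
        assert strip.shape[1] == 256

    def test_extremes_hit_colormap_ends(self, axis):
        f = field_at([axis.p_bound, axis.p_free])
        mmap = project_to_axis(f, axis)
        rgb, strip = colorize_metabolic(mmap)
        np.testing.assert_array_equal(rgb[0, 0], strip[0, 0])
        np.testing.assert_array_equal(rgb[0, 1], strip[0, -1])

    def test_missing_pixels_black(self, axis):
        f = field_at([(np.nan, np.nan), axis.p_free])
        mmap = project_to_axis(f, axis)
        rgb, _ = colorize_metabolic(mmap)
        np.testing.assert_array_equal(rgb[0, 0], [0, 0, 0])

    def test_unknown_colormap_rejected(self, axis):
        mmap = project_to_axis(field_at([axis.p_free]), axis)
        with pytest.raises(ValueError, match="colormap"):
            colorize_metabolic(mmap, "no-such-map")


class TestOuterRimMask:
    def test_overlaps_phantom_rim(self, phantom, noiseless_cube):
        f = decay_to_phasor(noiseless_cube)
        mask = outer_rim_mask(f.intensity, rim_width=6)
        gt = phantom.label_image == 1
        iou = (mask & gt).sum() / (mask | gt).sum()
        assert iou >= 0.8

    def test_huge_rim_width_covers_whole_object(self, noiseless_cube):
        f = decay_to_phasor(noiseless_cube)
        full = outer_rim_mask(f.intensity, rim_width=30)
        fg = f.intensity > 0
        assert (full & fg).sum() == full.sum()
        assert full.sum() == pytest.approx(fg.sum(), rel=0.01)

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            outer_rim_mask(np.zeros((16, 16)), rim_width=2)


class TestAgeSeries:
    def test_single_record_degenerate_summary(self):
        s = summarize_age_series([(55.0, 2.0)])
        row = s.table.iloc[0]
        assert row["n"] == 1
        assert row["q25"] == row["median"] == row["q75"] == 2.0
        assert row["whisker"] == 0.0

    def test_median_of_five(self):
        s = summarize_age_series([(40, v) for v in (1, 2, 3, 4, 5)])
        assert s.table.iloc[0]["median"] == 3
        assert s.table.iloc[0]["n"] == 5

    def test_linear_interpolation_quartiles(self):
        s = summarize_age_series([(40, v) for v in (1.0, 2.0, 3.0, 4.0)])
        assert s.table.iloc[0]["q25"] == pytest.approx(1.75)
        assert s.table.iloc[0]["q75"] == pytest.approx(3.25)

    def test_whisker_is_1p5_sd(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        s = summarize_age_series([(40, v) for v in vals])
        assert s.table.iloc[0]["whisker"] == pytest.approx(1.5 * np.std(vals))

    def test_empty_bins_omitted(self):
        s = summarize_age_series([(40, 1.0), (160, 2.0)])
        assert len(s.table) == 2
        assert list(s.table["age_min"]) == [30, 150]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_age_series([])

    def test_dataframe_input(self):
        df = pd.DataFrame({"age_days": [40, 45], "fb_ratio": [1.0, 3.0]})
        s = summarize_age_series(df)
        assert s.table.iloc[0]["median"] == 2.0
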