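"""Phasor transform, universal circle, calibration, lifetime inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoidphasor import (
    DecayCube,
    apply_calibration,
    decay_to_phasor,
    derive_calibration,
    lifetime_from_phasor,
    make_reference_decay,
    median_filter_phasor,
    universal_circle_point,
)
from conftest import OMEGA, mono_exp_cube


class TestUniversalCircle:
    @pytest.mark.parametrize(
        "tau, expected",
        [(0.0, (1.0, 0.0)), (1e9, (0.0, 0.0)), (1.0 / OMEGA, (0.5, 0.5))],
    )
    def test_landmark_points(self, tau, expected):
        g, s = universal_circle_point(tau, OMEGA)
        assert (g, s) == pytest.approx(expected, abs=1e-6)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            universal_circle_point(-0.1, OMEGA)

    @given(tau=st.floats(0.01, 6.0))
    @settings(deadline=None)
    def test_points_lie_on_circle(self, tau):
        g, s = universal_circle_point(tau, OMEGA)
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-12)


class TestDecayToPhasor:
    def test_delta_decay_near_zero_lifetime_point(self):
        counts = np.zeros((2, 2, 64))
        counts[..., 0] = 100.0
        cube = DecayCube(counts=counts, rep_period=12.5)
        f = decay_to_phasor(cube)
        t0 = cube.bin_centers[0]
        assert f.g[0, 0] == pytest.approx(np.cos(OMEGA * t0), abs=1e-12)
        assert f.s[0, 0] == pytest.approx(np.sin(OMEGA * t0), abs=1e-12)

    def test_flat_histogram_maps_to_origin(self):
        cube = DecayCube(counts=np.ones((2, 2, 64)), rep_period=12.5)
        f = decay_to_phasor(cube)
        # bin centers are symmetric over the period, so the sums vanish
        np.testing.assert_allclose(f.g, 0.0, atol=1e-12)
        np.testing.assert_allclose(f.s, 0.0, atol=1e-12)

    @pytest.mark.parametrize("tau", [0.4, 2.5, 3.4])
    def test_mono_exponential_matches_closed_form(self, tau):
        """Discrete phasor sum vs the independent brute-force oracle and the
        continuous closed form (within discretization tolerance)."""
        cube = mono_exp_cube(tau, n_bins=256)
        f = decay_to_phasor(cube)
        # brute-force oracle: direct sum over bins
        h = cube.counts[0, 0]
        t = cube.bin_centers
        g_oracle = (h * np.cos(OMEGA * t)).sum() / h.sum()
        s_oracle = (h * np.sin(OMEGA * t)).sum() / h.sum()
        assert f.g[0, 0] == pytest.approx(g_oracle, abs=1e-12)
        assert f.s[0, 0] == pytest.approx(s_oracle, abs=1e-12)
        g_cont, s_cont = universal_circle_point(tau, OMEGA)
        assert f.g[0, 0] == pytest.approx(g_cont, abs=1e-3)
        assert f.s[0, 0] == pytest.approx(s_cont, abs=1e-3)

    def test_intensity_conserved_exactly(self, noiseless_cube):
        f = decay_to_phasor(noiseless_cube)
        assert f.intensity.sum() == pytest.approx(noiseless_cube.counts.sum(), rel=0)

    def test_zero_intensity_pixels_missing_not_origin(self, phantom, noiseless_cube):
        f = decay_to_phasor(noiseless_cube)
        assert np.all(np.isnan(f.g[~phantom.foreground]))
        assert np.all(np.isnan(f.s[~phantom.foreground]))
        assert np.all(~np.isnan(f.g[phantom.foreground]))

    def test_all_zero_cube_warns_and_returns_missing(self):
        cube = DecayCube(counts=np.zeros((2, 2, 32)), rep_period=12.5)
        with pytest.warns(UserWarning, match="no photons"):
            f = decay_to_phasor(cube)
        assert np.all(np.isnan(f.g))

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(0.1, 10.0),
        tau_a=st.floats(0.2, 1.0),
        tau_b=st.floats(1.5, 5.0),
    )
    @settings(deadline=None, max_examples=25)
    def test_linearity_of_mixtures(self, a, b, tau_a, tau_b):
        """Phasor of a*A + b*B is the intensity-weighted convex combination
        of the component phasors: proportions mix linearly on the plot."""
        cube_a = mono_exp_cube(tau_a, n_bins=64, shape=(1, 1), photons=1.0)
        cube_b = mono_exp_cube(tau_b, n_bins=64, shape=(1, 1), photons=1.0)
        mixed = DecayCube(
            counts=a * cube_a.counts + b * cube_b.counts, rep_period=12.5
        )
        fa, fb, fm = (decay_to_phasor(c) for c in (cube_a, cube_b, mixed))
        w = a / (a + b)
        assert fm.g[0, 0] == pytest.approx(
            w * fa.g[0, 0] + (1 - w) * fb.g[0, 0], abs=1e-9
        )
        assert fm.s[0, 0] == pytest.approx(
            w * fa.s[0, 0] + (1 - w) * fb.s[0, 0], abs=1e-9
        )


class TestCalibration:
    def test_undistorted_reference_gives_near_identity(self, reference_field):
        cal = derive_calibration(reference_field, tau_ref=2.5)
        assert cal.phase_correction == pytest.approx(0.0, abs=1e-3)
        assert cal.modulation_correction == pytest.approx(1.0, abs=1e-3)

    def test_roundtrip_recovers_injected_distortion(self):
        ref = make_reference_decay(2.5, 256, phase_offset=0.3,
                                   modulation_scale=0.8, frame_shape=(4, 4))
        applied = ref.meta["applied_phase_offset"]
        distorted = decay_to_phasor(ref)
        clean = decay_to_phasor(make_reference_decay(2.5, 256, frame_shape=(4, 4)))
        cal_d = derive_calibration(distorted, 2.5)
        cal_c = derive_calibration(clean, 2.5)
        # corrections differ from the clean ones by exactly the negation /
        # inverse of the injected distortion
        assert cal_d.phase_correction - cal_c.phase_correction == pytest.approx(
            -applied, abs=1e-6
        )
        assert cal_d.modulation_correction / cal_c.modulation_correction == (
            pytest.approx(1 / 0.8, abs=1e-6)
        )

    def test_calibrated_mono_exponential_on_circle(self):
        distorted = decay_to_phasor(
            make_reference_decay(2.5, 256, phase_offset=0.3,
                                 modulation_scale=0.8, frame_shape=(4, 4))
        )
        cal = derive_calibration(distorted, 2.5)
        f = apply_calibration(distorted, cal)
        g_t, s_t = universal_circle_point(2.5, OMEGA)
        np.testing.assert_allclose(f.g, g_t, atol=1e-3)
        np.testing.assert_allclose(f.s, s_t, atol=1e-3)
        assert np.all(np.abs((f.g - 0.5) ** 2 + f.s**2 - 0.25) < 1e-3)

    def test_intensity_unchanged_by_calibration(self, reference_field):
        cal = derive_calibration(reference_field, 2.5)
        f = apply_calibration(reference_field, cal)
        np.testing.assert_array_equal(f.intensity, reference_field.intensity)

    def test_double_calibration_rejected(self, reference_field):
        cal = derive_calibration(reference_field, 2.5)
        f = apply_calibration(reference_field, cal)
        with pytest.raises(ValueError, match="already calibrated"):
            apply_calibration(f, cal)

    def test_omega_mismatch_rejected(self, reference_field):
        other = decay_to_phasor(make_reference_decay(2.5, 256, rep_period=10.0,
                                                     frame_shape=(2, 2)))
        cal = derive_calibration(other, 2.5)
        with pytest.raises(ValueError, match="omega"):
            apply_calibration(reference_field, cal)

    def test_invalid_tau_ref_rejected(self, reference_field):
        with pytest.raises(ValueError):
            derive_calibration(reference_field, tau_ref=0.0)


class TestLifetimeInversion:
    @given(tau=st.floats(0.05, 6.25))
    @settings(deadline=None)
    def test_roundtrip_identity(self, tau):
        g, s = universal_circle_point(tau, OMEGA)
        tp, tm = lifetime_from_phasor(g, s, OMEGA)
        assert tp == pytest.approx(tau, abs=1e-9)
        assert tm == pytest.approx(tau, abs=1e-9)

    def test_mixture_lifetimes_bracketed_and_distinct(self):
        """For a 50/50 two-component pixel the phase and modulation
        lifetimes disagree, both lying between the component lifetimes."""
        cube_a = mono_exp_cube(0.4, shape=(1, 1))
        cube_b = mono_exp_cube(3.4, shape=(1, 1))
        mixed = DecayCube(
            counts=0.5 * (cube_a.counts + cube_b.counts), rep_period=12.5
        )
        f = decay_to_phasor(mixed)
        tp, tm = lifetime_from_phasor(f.g[0, 0], f.s[0, 0], OMEGA)
        assert tp != pytest.approx(tm, abs=1e-3)
        assert 0.4 < tp < 3.4
        assert 0.4 < tm < 3.4

    def test_undefined_cases_reported_as_nan(self):
        tp, _ = lifetime_from_phasor(-0.1, 0.2, OMEGA)
        assert np.isnan(tp)
        _, tm = lifetime_from_phasor(0.9, 0.9, OMEGA)  # modulus > 1
        assert np.isnan(tm)


class TestMedianFilter:
    def test_window_one_is_identity(self, reference_field):
        f = median_filter_phasor(reference_field, window=1)
        np.testing.assert_array_equal(f.g, reference_field.g)

    def test_constant_field_unchanged(self, reference_field):
        f = median_filter_phasor(reference_field, window=3)
        np.testing.assert_allclose(f.g, reference_field.g, atol=1e-12)

    def test_outlier_replaced_by_neighborhood_median(self):
        g = np.full((5, 5), 0.4)
        s = np.full((5, 5), 0.3)
        g[2, 2] = 0.9
        from organoidphasor import PhasorField

        f = PhasorField(g=g, s=s, intensity=np.ones((5, 5)), omega=OMEGA)
        out = median_filter_phasor(f, window=3)
        assert out.g[2, 2] == pytest.approx(0.4)
        np.testing.assert_array_equal(out.intensity, f.intensity)

    def test_missing_pixels_stay_missing_and_excluded(self):
        from organoidphasor import PhasorField

        g = np.full((3, 3), 0.4)
        g[1, 1] = np.nan
        f = PhasorField(g=g, s=g.copy(), intensity=np.ones((3, 3)), omega=OMEGA)
        out = median_filter_phasor(f, window=3)
        assert np.isnan(out.g[1, 1])
        assert out.g[0, 0] == pytest.approx(0.4)

    def test_even_window_rejected(self, reference_field):
        with pytest.raises(ValueError):
            median_filter_phasor(reference_field, window=4)
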