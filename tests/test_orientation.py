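import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from tensionmap.circular import axial_difference
from tensionmap.orientation import (
    AlphaTriplet,
    DipoleModelParams,
    PolarizationTriplet,
    SinusoidFit,
    amplitude_offset,
    fit_image_triplet,
    fit_three_point,
    forward_intensity,
    polarization_response,
    theta_from_fit,
)


def dense_lstsq_phi(phi_true, amplitude, offset, alphas_deg=None):
    """Independent oracle: linear least squares on a dense alpha sweep.

    I(alpha) = k0 + k1*cos(2a) + k2*sin(2a) with k1 = -(A/2)cos(2phi),
    k2 = -(A/2)sin(2phi); fit by lstsq on 1-degree samples of the exact
    sinusoid and read phi off the harmonic coefficients.
    """
    a = np.arange(0.0, 180.0, 1.0) if alphas_deg is None else np.asarray(alphas_deg)
    y = amplitude * np.sin(np.radians(a - phi_true)) ** 2 + offset
    ar = np.radians(a)
    design = np.column_stack([np.ones_like(ar), np.cos(2 * ar), np.sin(2 * ar)])
    k0, k1, k2 = np.linalg.lstsq(design, y, rcond=None)[0]
    phi = np.degrees(np.arctan2(-k2, -k1)) / 2.0
    amp = 2.0 * np.hypot(k1, k2)
    return np.mod(phi, 180.0), amp, k0 - amp / 2.0


class TestAlphaTriplet:
    def test_default_valid(self):
        t = AlphaTriplet(17, 77, 137)
        assert_allclose(t.as_array(), [17, 77, 137])

    def test_reduction_mod_180(self):
        t = AlphaTriplet(197, 77, 317)
        assert_allclose(sorted(t.as_array()), [17, 77, 137])

    def test_invalid_spacing_raises(self):
        with pytest.raises(ValueError, match="60 degrees"):
            AlphaTriplet(0, 50, 120)


class TestForwardIntensity:
    def test_vertical_force_has_no_polarization_dependence(self):
        for alpha in (0.0, 33.0, 121.5):
            assert forward_intensity(12.0, 0.0, 100.0, alpha) == pytest.approx(100.0)

    def test_in_plane_force_parallel_excitation_minimum(self):
        assert forward_intensity(77.0, 90.0, 100.0, 77.0, b=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        # A = 93.1, c = 6.9 at theta=90, i_max=100, b=0.069
        a, c = amplitude_offset(90.0, 100.0, 0.069)
        assert a == pytest.approx(93.1)
        assert c == pytest.approx(6.9)
        expected = 93.1 * np.sin(np.radians(60.0)) ** 2 + 6.9
        assert forward_intensity(30.0, 90.0, 100.0, 90.0) == pytest.approx(expected)

    def test_periodic_in_alpha(self):
        v1 = forward_intensity(30.0, 60.0, 500.0, 25.0)
        v2 = forward_intensity(30.0, 60.0, 500.0, 205.0)
        assert v1 == pytest.approx(v2)


class TestFitThreePoint:
    def test_constant_input_orientation_undefined(self):
        fit = fit_three_point(100.0, 100.0, 100.0)
        assert not fit.orientation_defined
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.offset == pytest.approx(100.0)
        assert fit.i_max == pytest.approx(100.0)
        assert np.isnan(fit.phi)

    def test_known_triplet(self):
        fit = fit_three_point(125.0, 50.0, 125.0)
        assert fit.phi == pytest.approx(77.0)
        assert fit.amplitude == pytest.approx(100.0)
        assert fit.offset == pytest.approx(50.0)
        assert fit.i_max == pytest.approx(150.0)

    def test_derived_forward_oracle(self):
        vals = [80.0 * np.sin(np.radians(a - 30.0)) ** 2 + 20.0 for a in (17.0, 77.0, 137.0)]
        fit = fit_three_point(*vals)
        assert fit.phi == pytest.approx(30.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(80.0, rel=1e-6)
        assert fit.offset == pytest.approx(20.0, rel=1e-6)

    def test_negative_offset_flagged_invalid(self):
        # amplitude sinusoid dipping below zero
        vals = [100.0 * np.sin(np.radians(a - 40.0)) ** 2 - 10.0 for a in (17.0, 77.0, 137.0)]
        fit = fit_three_point(*vals)
        assert fit.orientation_defined
        assert fit.offset == pytest.approx(-10.0)
        assert not fit.valid

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            fit_three_point(np.nan, 1.0, 2.0)

    @given(
        phi=st.floats(0, 180, exclude_max=True),
        amplitude=st.floats(0.01, 1e4),
        offset=st.floats(0.01, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_exact_interpolation(self, phi, amplitude, offset):
        al = AlphaTriplet(17, 77, 137)
        vals = [amplitude * np.sin(np.radians(a - phi)) ** 2 + offset for a in al.as_array()]
        fit = fit_three_point(*vals, al)
        if fit.amplitude / fit.i_max < 1e-3:
            return  # amplitude degenerate relative to scale; phi undefined
        assert abs(axial_difference(fit.phi, phi)) < 1e-6
        assert fit.amplitude == pytest.approx(amplitude, rel=1e-9, abs=1e-9)
        assert fit.offset == pytest.approx(offset, rel=1e-9, abs=1e-9)

    @given(
        phi=st.floats(0, 180, exclude_max=True),
        amplitude=st.floats(1.0, 1e3),
        offset=st.floats(0.1, 1e3),
        delta=st.floats(-180, 180),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_covariance(self, phi, amplitude, offset, delta):
        al0 = AlphaTriplet(17, 77, 137)
        al1 = AlphaTriplet(17 + delta, 77 + delta, 137 + delta)
        vals = [
            amplitude * np.sin(np.radians(a - (phi + delta))) ** 2 + offset
            for a in (17 + delta, 77 + delta, 137 + delta)
        ]
        fit = fit_three_point(*vals, al1)
        assert fit.amplitude == pytest.approx(amplitude, rel=1e-6)
        assert fit.offset == pytest.approx(offset, rel=1e-6, abs=1e-6)
        assert abs(axial_difference(fit.phi, phi + delta)) < 1e-6

    def test_oracle_equivalence_small_sample(self, rng):
        al = AlphaTriplet(17, 77, 137)
        for _ in range(100):
            phi = rng.uniform(0, 180)
            amp = rng.uniform(1, 100)
            off = rng.uniform(0.1, 100)
            vals = [amp * np.sin(np.radians(a - phi)) ** 2 + off for a in al.as_array()]
            fit = fit_three_point(*vals, al)
            phi_o, amp_o, off_o = dense_lstsq_phi(phi, amp, off)
            assert abs(axial_difference(fit.phi, phi_o)) < 1e-6
            assert fit.amplitude == pytest.approx(amp_o, rel=1e-6)
            assert fit.offset == pytest.approx(off_o, rel=1e-6, abs=1e-6)


class TestThetaFromFit:
    def test_zero_amplitude_is_vertical(self):
        fit = SinusoidFit(amplitude=0.0, offset=100.0, phi=float("nan"))
        assert theta_from_fit(fit) == pytest.approx(0.0)

    def test_boundary_in_plane(self):
        fit = SinusoidFit(amplitude=93.1, offset=6.9, phi=0.0)
        assert theta_from_fit(fit) == pytest.approx(90.0)

    def test_intermediate_inverse(self):
        fit = SinusoidFit(amplitude=46.55, offset=53.45, phi=0.0)
        assert theta_from_fit(fit) == pytest.approx(45.0)

    @pytest.mark.parametrize("theta_true", [5.0, 22.5, 45.0, 67.5, 88.0])
    def test_roundtrip_through_forward_model(self, theta_true):
        a, c = amplitude_offset(theta_true, 1000.0)
        fit = SinusoidFit(amplitude=float(a), offset=float(c), phi=0.0)
        assert theta_from_fit(fit) == pytest.approx(theta_true, abs=1e-9)

    def test_nonpositive_offset_raises(self):
        fit = SinusoidFit(amplitude=10.0, offset=-1.0, phi=0.0, valid=False)
        with pytest.raises(ValueError):
            theta_from_fit(fit)

    def test_monotone_decreasing_in_offset(self):
        i_max = 100.0
        offsets = np.linspace(7.0, 99.9, 40)
        thetas = [
            theta_from_fit(SinusoidFit(amplitude=i_max - c, offset=c, phi=0.0)) for c in offsets
        ]
        assert np.all(np.diff(thetas) < 0)


class TestFitImageTriplet:
    @staticmethod
    def _triplet_from_maps(phi, theta, i_max, alphas):
        imgs = np.stack(
            [forward_intensity(phi, theta, i_max, a) for a in alphas.as_array()]
        )
        return PolarizationTriplet(images=imgs, alphas=alphas)

    def test_all_zero_images_all_invalid(self, alphas):
        triplet = PolarizationTriplet(images=np.zeros((3, 8, 8)), alphas=alphas)
        omap = fit_image_triplet(triplet)
        assert not omap.valid.any()

    def test_uniform_scene_constant_phi(self, alphas):
        shape = (16, 16)
        triplet = self._triplet_from_maps(
            np.full(shape, 45.0), np.full(shape, 90.0), np.full(shape, 1000.0), alphas
        )
        omap = fit_image_triplet(triplet)
        assert omap.valid.any()
        assert_allclose(omap.phi[omap.valid], 45.0, atol=1e-9)
        assert_allclose(omap.theta[omap.valid], 90.0, atol=1e-9)

    def test_known_map_recovered(self, alphas, rng):
        shape = (24, 24)
        phi = rng.uniform(0, 180, shape)
        theta = rng.uniform(20, 90, shape)
        i_max = rng.uniform(500, 2000, shape)
        triplet = self._triplet_from_maps(phi, theta, i_max, alphas)
        omap = fit_image_triplet(triplet, mask_quantile=0.0)
        v = omap.valid
        assert v.mean() > 0.95
        assert np.nanmax(np.abs(axial_difference(omap.phi[v], phi[v]))) < 1e-6
        assert np.nanmax(np.abs(omap.theta[v] - theta[v])) < 1e-6
        assert_allclose(omap.i_max[v], i_max[v], rtol=1e-9)

    def test_i_avg_channel(self, alphas):
        triplet = PolarizationTriplet(images=np.full((3, 4, 4), 7.0), alphas=alphas)
        omap = fit_image_triplet(triplet)
        assert_allclose(omap.i_avg, 7.0)

    def test_mask_quantile_masks_dim_pixels(self, alphas):
        shape = (10, 10)
        i_max = np.full(shape, 100.0)
        i_max[:5] = 10.0  # dim half
        triplet = self._triplet_from_maps(
            np.full(shape, 30.0), np.full(shape, 60.0), i_max, alphas
        )
        omap = fit_image_triplet(triplet, mask_quantile=60.0)
        assert not omap.valid[:5].any()
        assert omap.valid[5:].all()

    def test_shape_mismatch_raises(self, alphas):
        with pytest.raises(ValueError):
            PolarizationTriplet(images=np.zeros((2, 8, 8)), alphas=alphas)


class TestPolarizationResponse:
    def _make_map(self, amplitude, offset, shape=(10, 10)):
        a = np.full(shape, amplitude, dtype=float)
        c = np.full(shape, offset, dtype=float)
        from tensionmap.orientation import OrientationMap

        return OrientationMap(
            phi=np.zeros(shape),
            theta=np.zeros(shape),
            amplitude=a,
            offset=c,
            i_max=a + c,
            valid=np.ones(shape, dtype=bool),
        )

    def test_zero_amplitude_gives_zero(self):
        omap = self._make_map(0.0, 11.0)
        cell = np.zeros((10, 10), bool)
        cell[:5] = True
        val, bg = polarization_response(omap, cell, ~cell)
        assert val == 0.0
        assert bg == 0.0

    def test_uniform_arithmetic(self):
        omap = self._make_map(10.0, 4.0)
        cell = np.zeros((10, 10), bool)
        cell[:5] = True
        val, _ = polarization_response(omap, cell, ~cell)
        assert val == pytest.approx(2.0)

    def test_cell_exceeds_background(self, platelet_scene, alphas):
        from tests.conftest import render_and_fit

        omap = render_and_fit(platelet_scene)
        cell = platelet_scene.mask
        bg = ~cell
        val, bgval = polarization_response(omap, cell, bg)
        assert val > 10 * max(bgval, 1e-9)

    def test_empty_mask_raises(self):
        omap = self._make_map(1.0, 1.0)
        with pytest.raises(ValueError):
            polarization_response(omap, np.zeros((10, 10), bool), np.ones((10, 10), bool))

    def test_overlapping_masks_raise(self):
        omap = self._make_map(1.0, 1.0)
        m = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            polarization_response(omap, m, m)


class TestInvariants:
    def test_i_max_independent_of_phi(self):
        for phi in np.arange(0, 180, 12.5):
            a, c = amplitude_offset(63.0, 850.0)
            al = AlphaTriplet(17, 77, 137)
            vals = [float(forward_intensity(phi, 63.0, 850.0, x)) for x in al.as_array()]
            fit = fit_three_point(*vals, al)
            assert fit.i_max == pytest.approx(850.0, rel=1e-9)
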