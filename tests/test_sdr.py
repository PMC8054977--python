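"""Spatial-domain reconstruction: coefficients, superposition, deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdrsim as s
from sdrsim.errors import InvalidParameterError, UnsupportedConfigurationError
from sdrsim.sdr import sdr_coefficients, sdr_superpose, wiener_deconvolve


def brute_force_identity_error(pattern, grid, n_pairs, rng):
    """Independent check of the superposition identity: evaluate
    sum_j c_j(x) * I(x' - delta_j) at random pixel/continuous-point pairs
    and compare with the target function 1 + cos(2 pi k0.(x - x'))."""
    coeffs = sdr_coefficients(pattern, grid)
    kx, ky = pattern.wavevector_cyc_per_nm
    i0, m = pattern.mean_intensity, pattern.modulation_depth
    phi0 = pattern.initial_phase_rad

    ii = rng.integers(0, grid.n_rows, n_pairs)
    jj = rng.integers(0, grid.n_cols, n_pairs)
    x = grid.x_nm[ii, jj]
    y = grid.y_nm[ii, jj]
    # x' need not lie on the pixel raster
    xp = rng.uniform(x.min(), x.max(), n_pairs)
    yp = rng.uniform(y.min(), y.max(), n_pairs)

    total = np.zeros(n_pairs)
    for j, psi in enumerate(pattern.phase_shifts_rad):
        illum = i0 * (1 + m * np.cos(2 * np.pi * (kx * xp + ky * yp) + phi0 - psi))
        total += coeffs.fields[j][ii, jj] * illum
    target = 1 + np.cos(2 * np.pi * (kx * (x - xp) + ky * (y - yp)))
    return float(np.max(np.abs(total - target)))


class TestCoefficients:
    def test_peak_value_at_zero_phase(self):
        """At m=1, I0=1 and a point where the pattern phase is zero,
        c_1 = (1 + 2)/3 = 1 exactly."""
        grid = s.Grid2D(16, 16, 10.0)
        pat = s.SinusoidPattern(1.0, 1.0, 1e9, 0.0, initial_phase_rad=0.0)
        coeffs = sdr_coefficients(pat, grid)
        assert coeffs.fields[0][grid.origin] == pytest.approx(1.0, rel=1e-12)

    def test_fields_sum_to_reciprocal_intensity(self, grid256, rng):
        pat = s.SinusoidPattern(250.0, 0.7, 233.0, 41.0, initial_phase_rad=1.1)
        coeffs = sdr_coefficients(pat, grid256)
        total = coeffs.fields.sum(axis=0)
        ii = rng.integers(0, 256, 1000)
        jj = rng.integers(0, 256, 1000)
        np.testing.assert_allclose(total[ii, jj], 1.0 / 250.0, rtol=1e-9)

    def test_fields_bounded_by_raised_cosine_range(self, grid256):
        i0, m = 2.0, 0.5
        pat = s.SinusoidPattern(i0, m, 220.0, 10.0)
        coeffs = sdr_coefficients(pat, grid256)
        lo = (1 - 2 / m) / (3 * i0)
        hi = (1 + 2 / m) / (3 * i0)
        assert coeffs.fields.min() >= lo - 1e-12
        assert coeffs.fields.max() <= hi + 1e-12

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(
        m=st.floats(0.1, 1.0),
        period=st.floats(150.0, 2000.0),
        phi0=st.floats(0.0, 6.28),
        theta=st.floats(0.0, 180.0),
    )
    def test_superposition_identity_property(self, m, period, phi0, theta):
        """The defining identity holds for any valid (m, T, phi0):
        sum_j c_j(x) I(x'-d_j) = 1 + cos(2 pi k0.(x-x')) to 1e-9."""
        grid = s.Grid2D(32, 32, 30.0)
        pat = s.SinusoidPattern(1.3, m, period, theta, initial_phase_rad=phi0)
        err = brute_force_identity_error(pat, grid, 200, np.random.default_rng(0))
        assert err < 1e-9

    def test_non_three_phase_configuration_rejected(self, grid128):
        pat = s.SinusoidPattern(1.0, 0.9, 220.0, 0.0, phase_shifts_rad=(0.0, np.pi))
        with pytest.raises(UnsupportedConfigurationError):
            sdr_coefficients(pat, grid128)

    def test_coefficients_cached_per_grid_and_pattern(self, grid128):
        pat = s.SinusoidPattern(1.0, 0.9, 220.0, 0.0)
        assert sdr_coefficients(pat, grid128) is sdr_coefficients(pat, grid128)


class TestSuperposition:
    def test_zero_frames_give_zero_result(self, grid128, psf200):
        pats = s.default_patterns(grid128)
        stack = s.SIMStack(np.zeros((9, 128, 128)), pats, psf200, grid128)
        assert np.all(sdr_superpose(stack, 0) == 0)

    def test_point_source_yields_effective_psf(self, point_stack, psf200):
        """Pre-deconvolution SDR output of a delta emitter IS the analytic
        effective PSF — the spatial-domain resolution mechanism."""
        _, stack = point_stack
        for d in range(3):
            result = sdr_superpose(stack, d)
            expected = s.effective_psf(psf200, stack.patterns[d], stack.grid).values
            crop = (slice(18, -18),) * 2
            nrmse = np.sqrt(np.mean((result[crop] - expected[crop]) ** 2)) / expected.max()
            assert nrmse < 1e-6

    def test_uniform_object_gives_constant_result(self, grid256, psf200):
        pats = s.default_patterns(grid256)
        stack = s.simulate_sim_stack(s.make_uniform(grid256), pats, psf200)
        result = sdr_superpose(stack, 0)
        interior = result[32:-32, 32:-32]
        assert interior.std() / interior.mean() < 1e-6

    def test_no_fourier_transform_used(self, bead_scene_stack, monkeypatch):
        """Superposition is a pure pixel-wise multiply-accumulate: it must
        succeed even with the FFT disabled."""
        _, stack = bead_scene_stack
        s.sdr.clear_coefficient_cache()

        def _forbidden(*a, **k):
            raise AssertionError("FFT called during spatial superposition")

        monkeypatch.setattr(np.fft, "fft2", _forbidden)
        monkeypatch.setattr(np.fft, "ifft2", _forbidden)
        out = sdr_superpose(stack, 1)
        assert np.all(np.isfinite(out))


class TestWienerDeconvolution:
    def test_near_exact_inverse_when_noise_free(self, grid256, psf200, patterns256):
        # object kept band-limited (smooth 160 nm spots) so the inverse is
        # well posed inside the effective-OTF support
        obj = s.make_bead_field(
            grid256, n_beads=4, seed=9, margin_nm=700.0, bead_diameter_nm=160.0
        )
        p = s.effective_psf(psf200, patterns256, grid256).values
        blurred = s.simulate.fft_convolve(obj.image, p)
        recovered = wiener_deconvolve(blurred, p, w=1e-6)
        crop = (slice(20, -20),) * 2
        scale = np.sum(p)  # convolution kernel gain
        nrmse = np.sqrt(
            np.mean((recovered[crop] / scale - obj.image[crop]) ** 2)
        ) / obj.image.max()
        assert nrmse < 1e-3

    def test_zero_image_maps_to_zero(self, grid128, psf200):
        p = s.gaussian_psf_image(psf200, grid128, warn_truncation=False)
        out = wiener_deconvolve(np.zeros(grid128.shape), p, w=0.05)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linearity(self, grid128, psf200, rng):
        p = s.gaussian_psf_image(psf200, grid128, warn_truncation=False)
        x = rng.random(grid128.shape)
        a = wiener_deconvolve(3.0 * x, p, w=0.05)
        b = 3.0 * wiener_deconvolve(x, p, w=0.05)
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_nonpositive_regularization_rejected(self, grid128, psf200):
        p = s.gaussian_psf_image(psf200, grid128, warn_truncation=False)
        with pytest.raises(InvalidParameterError):
            wiener_deconvolve(np.ones(grid128.shape), p, w=0.0)


class TestFullReconstruction:
    def test_scaling_the_stack_scales_the_image(self, bead_scene_stack):
        _, stack = bead_scene_stack
        scaled = s.SIMStack(
            2.5 * stack.frames, stack.patterns, stack.psf, stack.grid
        )
        a = s.sdr_reconstruct(stack)
        b = s.sdr_reconstruct(scaled)
        np.testing.assert_allclose(b.sr_image, 2.5 * a.sr_image, rtol=1e-9, atol=1e-12)

    def test_nodeconv_point_response_is_combined_effective_psf(self, point_stack, psf200):
        _, stack = point_stack
        result = s.sdr_reconstruct(stack, deconvolve=False)
        assert result.method == "sdr-nodeconv"
        expected = s.effective_psf(psf200, stack.patterns, stack.grid).values
        crop = (slice(18, -18),) * 2
        nrmse = np.sqrt(np.mean((result.sr_image[crop] - expected[crop]) ** 2)) / expected.max()
        assert nrmse < 1e-6

    def test_two_point_resolved_only_after_reconstruction(self, psf200):
        grid = s.Grid2D(256, 256, 32.5)
        pats = s.default_patterns(grid)
        obj = s.make_two_point(grid, 130.0, 0.0)
        stack = s.simulate_sim_stack(obj, pats, psf200)
        centers = obj.truth["centers_nm"]
        sr = s.sdr_reconstruct(stack)
        wf = s.widefield_reconstruct(stack)
        assert s.two_point_dip(sr.sr_image, grid, centers) >= 0.2
        assert s.two_point_dip(wf.sr_image, grid, centers) == 0.0

    def test_provenance_recorded(self, bead_scene_stack):
        _, stack = bead_scene_stack
        result = s.sdr_reconstruct(stack, wiener_w=0.07)
        assert result.params["wiener_w"] == 0.07
        assert result.params["patterns"] == stack.patterns
        assert result.params["psf_fwhm_nm"] == stack.psf.fwhm_nm
        assert result.sr_image.min() >= 0.0
        assert "unclipped" in result.params
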