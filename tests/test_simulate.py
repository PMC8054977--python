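"""Forward simulator: scenes, raw-stack formation, noise determinism."""

import numpy as np
import pytest

import sdrsim as s
from sdrsim.errors import InvalidParameterError, PackingError
from sdrsim.simulate import carrier_pixels


class TestBeadField:
    def test_contract_counts_and_separation(self, grid256):
        obj = s.make_bead_field(
            grid256, n_beads=12, min_separation_nm=500.0, seed=3, margin_nm=600.0
        )
        centers = np.asarray(obj.truth["centers_nm"])
        assert centers.shape == (12, 2)
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 500.0
        assert all(grid256.contains_nm(cx, cy) for cx, cy in centers)

    def test_same_seed_reproduces_scene(self, grid256):
        a = s.make_bead_field(grid256, n_beads=5, seed=7, margin_nm=600.0)
        b = s.make_bead_field(grid256, n_beads=5, seed=7, margin_nm=600.0)
        np.testing.assert_array_equal(a.image, b.image)
        assert a.truth == b.truth

    def test_infeasible_packing_raises(self, grid128):
        with pytest.raises(PackingError, match="attempts"):
            s.make_bead_field(
                grid128, n_beads=100, min_separation_nm=2000.0, seed=0,
                margin_nm=300.0, max_attempts_per_bead=20,
            )


class TestTwoPoint:
    def test_separation_contract(self, grid256):
        obj = s.make_two_point(grid256, 130.0, 0.0)
        (x0, y0), (x1, y1) = obj.truth["centers_nm"]
        assert np.hypot(x1 - x0, y1 - y0) == pytest.approx(130.0, rel=1e-12)

    def test_axes_related_by_transpose(self, grid256):
        a = s.make_two_point(grid256, 260.0, 0.0)
        b = s.make_two_point(grid256, 260.0, 90.0)
        np.testing.assert_allclose(b.image, a.image.T, atol=1e-12)

    def test_subpixel_separation_rejected(self, grid256):
        with pytest.raises(InvalidParameterError):
            s.make_two_point(grid256, 10.0, 0.0)

    def test_out_of_bounds_separation_rejected(self, grid256):
        width = grid256.extent_nm[1]
        with pytest.raises(InvalidParameterError):
            s.make_two_point(grid256, width, 0.0)


class TestBarTarget:
    def test_binary_bars_with_half_duty(self, grid256):
        obj = s.make_bar_target(grid256, bar_period_nm=520.0, n_bars=3)
        assert set(np.unique(obj.image)) <= {0.0, 1.0}
        span_px = 3 * 520.0 / grid256.pixel_size_nm
        covered = span_px**2  # square target region in pixels
        on_fraction = obj.image.sum() / covered
        assert on_fraction == pytest.approx(0.5, abs=0.05)

    def test_subpixel_period_rejected(self, grid256):
        with pytest.raises(InvalidParameterError):
            s.make_bar_target(grid256, bar_period_nm=40.0)


class TestPatternSnapping:
    def test_default_patterns_have_integer_carriers(self, grid256, patterns256):
        for pat in patterns256:
            cy, cx = carrier_pixels(pat, grid256)
            assert cy == pytest.approx(round(cy), abs=1e-9)
            assert cx == pytest.approx(round(cx), abs=1e-9)

    def test_snap_changes_period_only_slightly(self, grid256):
        raw = s.SinusoidPattern(1.0, 0.9, 220.0, 60.0)
        snapped = s.snap_pattern_to_grid(raw, grid256)
        assert snapped.period_nm == pytest.approx(220.0, rel=0.05)
        assert snapped.orientation_deg == pytest.approx(60.0, abs=2.0)


class TestStackFormation:
    def test_zero_object_gives_zero_frames(self, grid128, psf200):
        pats = s.default_patterns(grid128)
        obj = s.SceneObject(np.zeros(grid128.shape), grid128, {"kind": "uniform", "level": 0})
        stack = s.simulate_sim_stack(obj, pats, psf200)
        assert np.all(stack.frames == 0)

    def test_noise_free_frames_linear_in_object(self, grid128, psf200):
        pats = s.default_patterns(grid128)
        obj = s.make_bead_field(grid128, n_beads=3, seed=5, margin_nm=500.0)
        scaled = s.SceneObject(3.5 * obj.image, grid128, obj.truth)
        a = s.simulate_sim_stack(obj, pats, psf200)
        b = s.simulate_sim_stack(scaled, pats, psf200)
        np.testing.assert_allclose(b.frames, 3.5 * a.frames, rtol=1e-10, atol=1e-12)

    def test_phase_sum_equals_widefield_times_three(self, bead_scene_stack, psf200):
        """The 120-degree phase steps cancel: one orientation's frames sum
        to 3*I0*(O conv H), the widefield baseline."""
        obj, stack = bead_scene_stack
        i0 = stack.patterns[0].mean_intensity
        h = s.gaussian_psf_image(psf200, stack.grid, warn_truncation=False)
        widefield = s.simulate.fft_convolve(obj.image, h) * i0
        for d in range(3):
            total = stack.orientation_frames(d).sum(axis=0)
            np.testing.assert_allclose(total, 3.0 * widefield, rtol=1e-6, atol=1e-9 * widefield.max())

    def test_uniform_object_modulation_contrast(self, grid256, psf200):
        """Raw-frame fringe contrast equals m * |OTF(k0)| (convolution
        theorem applied to the forward model)."""
        pats = s.default_patterns(grid256)
        obj = s.make_uniform(grid256)
        stack = s.simulate_sim_stack(obj, pats, psf200)
        h = s.gaussian_psf_image(psf200, grid256, warn_truncation=False)
        otf = s.otf_from_psf(h, grid256)
        for d in range(3):
            pat = stack.patterns[d]
            cy, cx = (round(v) for v in carrier_pixels(pat, grid256))
            expected = pat.modulation_depth * np.abs(otf[cy % 256, cx % 256])
            frame = stack.frame(d, 0)
            interior = frame[32:-32, 32:-32]
            measured = (interior.max() - interior.min()) / (interior.max() + interior.min())
            assert measured == pytest.approx(expected, rel=1e-3)

    def test_seeded_noise_bit_reproducible(self, grid128, psf200):
        pats = s.default_patterns(grid128)
        obj = s.make_bead_field(grid128, n_beads=3, seed=5, margin_nm=500.0)
        noise = s.NoiseModel(read_noise_sd=2.0, seed=42)
        a = s.simulate_sim_stack(obj, pats, psf200, noise)
        b = s.simulate_sim_stack(obj, pats, psf200, noise)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_noisy_mean_matches_noise_free(self, grid128, psf200):
        """Monte-Carlo: frame means under Poisson+read noise agree with the
        noise-free frame within 3 sd of the estimate. A bright scene is
        used so the zero-clip never truncates the noise distribution."""
        pats = s.default_patterns(grid128)
        obj = s.make_uniform(grid128)
        clean = s.simulate_sim_stack(obj, pats, psf200)
        means = []
        for seed in range(8):
            noisy = s.simulate_sim_stack(
                obj, pats, psf200, s.NoiseModel(read_noise_sd=2.0, seed=seed)
            )
            means.append(noisy.frames.mean())
        means = np.asarray(means)
        sd_est = means.std(ddof=1) / np.sqrt(means.size)
        assert abs(means.mean() - clean.frames.mean()) < 3 * sd_est + 0.05

    def test_mismatched_grid_rejected(self, grid128, grid256, psf200):
        pats = s.default_patterns(grid128)
        obj = s.make_uniform(grid256)
        frames = np.zeros((9, 128, 128))
        with pytest.raises(s.errors.ShapeError):
            s.SIMStack(frames=frames, patterns=pats, psf=psf200, grid=grid256)

    def test_widefield_is_phase_average(self, bead_scene_stack):
        _, stack = bead_scene_stack
        np.testing.assert_allclose(s.widefield_image(stack), stack.frames.mean(axis=0))
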