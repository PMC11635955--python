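import numpy as np
import pytest
from hypothesis import given, strategies as st

from fusedcae.metrics import radial_power_spectrum
from fusedcae.optics import PSFKernel
from fusedcae.phantoms import (ExposureSettings, SourceImage, capture,
                               convolve_reflect, long_exposure_reference,
                               make_fiber_phantom, make_fringe_phantom,
                               make_glyph_phantom, make_two_region_phantom)


class TestFringePhantom:
    def test_seven_lines_seven_minima(self):
        src = make_fringe_phantom((128, 128), pitch_um=3.0, n_lines=7)
        row = src.intensity[64]
        # count absorbing runs along a horizontal section
        dark = row < 1.0
        runs = np.diff(dark.astype(int))
        assert (runs == 1).sum() == 7

    def test_zero_depth_is_blank(self):
        src = make_fringe_phantom(depth=0.0)
        np.testing.assert_array_equal(src.intensity, 1.0)

    def test_single_opaque_line(self):
        src = make_fringe_phantom((64, 64), pitch_um=4.0, n_lines=1,
                                  depth=1.0)
        assert src.intensity.min() == 0.0
        assert (src.intensity == 0.0).any()
        assert (src.intensity[:, :16] == 1.0).all()

    def test_too_many_lines_rejected(self):
        with pytest.raises(ValueError):
            make_fringe_phantom((64, 64), pitch_um=3.0, n_lines=50)


class TestGlyphPhantom:
    def test_default_glyph_coverage(self):
        src = make_glyph_phantom((256, 256), "239")
        frac = (src.intensity < 1.0).mean()
        assert 0.01 < frac < 0.5

    def test_zero_depth_blank_and_determinism(self):
        assert (make_glyph_phantom(depth=0.0).intensity == 1.0).all()
        a = make_glyph_phantom((128, 128), "239")
        b = make_glyph_phantom((128, 128), "239")
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_unrenderable_glyph_rejected(self):
        with pytest.raises(ValueError, match="not renderable"):
            make_glyph_phantom(text="é")
        with pytest.raises(ValueError):
            make_glyph_phantom(text="")


class TestTwoRegionPhantom:
    def test_equal_ratios_without_texture(self):
        src, masks = make_two_region_phantom(ratio_a=0.7, ratio_b=0.7,
                                             texture_in_b=False)
        a = src.intensity[masks["a"]].mean()
        b = src.intensity[masks["b"]].mean()
        assert abs(a - b) < 1e-12

    def test_default_ratios_match_generator_contract(self):
        src, masks = make_two_region_phantom(seed=5)
        assert src.intensity[masks["a"]].mean() == pytest.approx(0.858,
                                                                 abs=1e-9)
        assert src.intensity[masks["b"]].mean() == pytest.approx(0.881,
                                                                 abs=1e-3)

    def test_texture_raises_high_frequency_energy(self):
        src, masks = make_two_region_phantom(seed=2)

        def hf_energy(mask):
            rows, cols = np.where(mask)
            crop = src.intensity[rows.min():rows.max() + 1,
                                 cols.min():cols.max() + 1]
            f, p = radial_power_spectrum(crop - crop.mean(),
                                         src.pixel_pitch_um, n_bins=16)
            return p[f > 0.2].sum()

        assert hf_energy(masks["b"]) > 10 * hf_energy(masks["a"])


class TestFiberPhantom:
    def test_zero_fibers_blank(self):
        assert (make_fiber_phantom(n_fibers=0).intensity == 1.0).all()

    def test_seed_determinism(self):
        a = make_fiber_phantom((96, 96), seed=3)
        b = make_fiber_phantom((96, 96), seed=3)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_more_fibers_more_coverage(self):
        few = (make_fiber_phantom((128, 128), n_fibers=5, seed=1)
               .intensity < 1.0).mean()
        many = (make_fiber_phantom((128, 128), n_fibers=20, seed=1)
                .intensity < 1.0).mean()
        assert many > few


class TestConvolution:
    def test_fft_equals_nested_loop_oracle(self, gauss_kernel_9):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.1, 1.0, (16, 16))
        k = gauss_kernel_9.grid[2:7, 2:7]
        k = k / k.sum()
        out = convolve_reflect(img, k)

        # independent brute-force convolution with symmetric padding
        pad = np.pad(img, 2, mode="symmetric")
        expected = np.zeros_like(img)
        for i in range(16):
            for j in range(16):
                acc = 0.0
                for u in range(5):
                    for v in range(5):
                        acc += k[u, v] * pad[i + 2 - (u - 2),
                                             j + 2 - (v - 2)]
                expected[i, j] = acc
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            convolve_reflect(np.ones((4, 4)), np.ones((9, 9)) / 81.0)


class TestCapture:
    def test_delta_scene_reproduces_kernel(self, delta_source,
                                           gauss_kernel_9,
                                           noiseless_exposure):
        shot = capture(delta_source, gauss_kernel_9, noiseless_exposure)
        flux = (noiseless_exposure.t_cap_ms
                * noiseless_exposure.photons_per_pixel_per_ms)
        window = shot.counts[28:37, 28:37] / flux
        np.testing.assert_allclose(window, gauss_kernel_9.grid, atol=1e-9)

    def test_uniform_scene_uniform_output(self, gauss_kernel_9,
                                          noiseless_exposure):
        src = SourceImage(np.full((32, 32), 0.8), 0.5)
        shot = capture(src, gauss_kernel_9, noiseless_exposure)
        np.testing.assert_allclose(shot.counts, shot.counts[16, 16],
                                   rtol=1e-9)

    def test_flux_conservation_interior(self, gauss_kernel_9):
        src = make_glyph_phantom((64, 64), "8")
        exp = ExposureSettings(bin_factor=1, noiseless=True)
        shot = capture(src, gauss_kernel_9, exp)
        flux = exp.t_cap_ms * exp.photons_per_pixel_per_ms
        # away from the frame edge, reflective padding conserves mass
        interior = np.s_[8:-8, 8:-8]
        assert shot.counts[interior].sum() == pytest.approx(
            flux * convolve_reflect(src.intensity,
                                    gauss_kernel_9.grid)[interior].sum(),
            rel=1e-9)

    def test_noisy_mean_matches_noiseless(self, gauss_kernel_9):
        src = SourceImage(np.linspace(0.2, 1.0, 16 * 16).reshape(16, 16),
                          0.5)
        base = ExposureSettings(bin_factor=1, noiseless=True,
                                read_noise_sd=0.0)
        truth = capture(src, gauss_kernel_9, base).counts
        n = 10_000
        rng = np.random.default_rng(123)
        draws = rng.poisson(truth, size=(n,) + truth.shape)
        mean = draws.mean(axis=0)
        se = np.sqrt(truth / n)
        assert (np.abs(mean - truth) <= 3.0 * se + 1e-9).mean() > 0.99

    def test_seed_reproducibility(self, gauss_kernel_9):
        src = make_fringe_phantom((64, 64))
        exp = ExposureSettings(seed=42)
        a = capture(src, gauss_kernel_9, exp)
        b = capture(src, gauss_kernel_9, exp)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_binning_shape(self, gauss_kernel_9):
        src = make_fringe_phantom((64, 64))
        shot = capture(src, gauss_kernel_9,
                       ExposureSettings(bin_factor=2, noiseless=True))
        assert shot.shape == (32, 32)
        assert shot.pixel_pitch_um == pytest.approx(1.0)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_capture_monotone_in_scene(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.1, 0.8, (16, 16))
        bump = base + rng.uniform(0.0, 0.2, (16, 16))
        k = PSFKernel(np.ones((3, 3)) / 9.0, 0.5)
        exp = ExposureSettings(bin_factor=1, noiseless=True)
        lo = capture(SourceImage(base, 0.5), k, exp).counts
        hi = capture(SourceImage(np.clip(bump, 0, 1), 0.5), k, exp).counts
        assert (hi >= lo - 1e-9).all()


class TestLongExposureReference:
    def test_requires_long_exposure(self, gauss_kernel_9):
        src = make_fringe_phantom((64, 64))
        with pytest.raises(ValueError):
            long_exposure_reference(src, gauss_kernel_9,
                                    ExposureSettings(t_cap_ms=20.0))

    def test_noiseless_equals_plain_capture(self, gauss_kernel_9):
        src = make_fringe_phantom((64, 64))
        exp = ExposureSettings(t_cap_ms=100.0, noiseless=True)
        lei = long_exposure_reference(src, gauss_kernel_9, exp)
        np.testing.assert_array_equal(lei.counts,
                                      capture(src, gauss_kernel_9,
                                              exp).counts)

    def test_longer_exposure_lower_relative_noise(self, gauss_kernel_9):
        src = make_fringe_phantom((64, 64))

        def rel_noise(t_cap):
            reps = np.stack([
                capture(src, gauss_kernel_9,
                        ExposureSettings(t_cap_ms=t_cap, seed=s)).counts
                for s in range(8)])
            return (reps.std(axis=0) / reps.mean(axis=0)).mean()

        assert rel_noise(100.0) < rel_noise(20.0)
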