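"""Degradation forward models against brute-force and closed-form oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from lumifuse import (
    DegradationSpec,
    Hypercube,
    WavelengthGrid,
    add_band_noise,
    downsample,
    extract_rgb,
    gaussian_blur,
    inject_dead_pixels,
    inject_specular,
    make_lr_hsi,
    upsample,
)
from lumifuse.degrade import gaussian_kernel_1d


def _constant_cube(value, shape, grid):
    return Hypercube(np.full(shape, value, dtype=np.float64), grid)


def _blur_oracle(img, kernel, sd):
    """Direct double-loop 2-D convolution with symmetric padding."""
    k1 = gaussian_kernel_1d(kernel, sd)
    k2 = np.outer(k1, k1)
    r = kernel // 2
    padded = np.pad(img, r, mode="symmetric")
    out = np.zeros_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.sum(padded[i:i + kernel, j:j + kernel] * k2)
    return out


class TestGaussianBlur:
    def test_constant_invariance(self, small_grid):
        cube = _constant_cube(0.37, (12, 12, 31), small_grid)
        out = gaussian_blur(cube, 5, 10.0)
        np.testing.assert_allclose(out.data, cube.data, atol=1e-12)

    def test_matches_bruteforce_oracle(self, small_grid, rng):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0                     # unit impulse
        rand = rng.random((9, 9))
        for base in (img, rand):
            cube = Hypercube(np.repeat(base[:, :, None], 2, axis=2),
                             WavelengthGrid([500.0, 600.0]))
            out = gaussian_blur(cube, 5, 10.0)
            oracle = _blur_oracle(base, 5, 10.0)
            np.testing.assert_allclose(out.data[:, :, 0], oracle, atol=1e-12)
            np.testing.assert_allclose(out.data[:, :, 1], oracle, atol=1e-12)

    def test_larger_kernel_removes_high_frequency(self, phantom_sample):
        def laplacian_var(cube):
            d = cube.data.astype(np.float64).mean(axis=2)
            lap = (np.roll(d, 1, 0) + np.roll(d, -1, 0) + np.roll(d, 1, 1)
                   + np.roll(d, -1, 1) - 4 * d)
            return lap[2:-2, 2:-2].var()

        small = gaussian_blur(phantom_sample.cube, 5, 10.0)
        big = gaussian_blur(phantom_sample.cube, 35, 10.0)
        assert laplacian_var(big) < laplacian_var(small)

    def test_mean_preserved(self, rng, small_grid):
        cube = Hypercube(rng.random((16, 16, 31)), small_grid)
        out = gaussian_blur(cube, 7, 3.0)
        np.testing.assert_allclose(out.data.mean(axis=(0, 1)),
                                   cube.data.mean(axis=(0, 1)), atol=1e-9)

    def test_even_kernel_rejected(self, random_cube):
        with pytest.raises(ValueError):
            gaussian_blur(random_cube, 4, 10.0)


class TestResampling:
    def test_downsample_shapes_and_constant(self, small_grid):
        cube = _constant_cube(0.5, (448, 448, 2), WavelengthGrid([500.0, 600.0]))
        out = downsample(cube, 4)
        assert out.shape == (112, 112, 2)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-12)
        with pytest.raises(ValueError):
            downsample(_constant_cube(0.5, (9, 9, 2), WavelengthGrid([500.0, 600.0])), 4)

    def test_downsample_ramp_closed_form(self):
        rows, cols = np.mgrid[0:16, 0:16].astype(np.float64)
        ramp = (rows + cols)[:, :, None]
        cube = Hypercube(ramp, WavelengthGrid([500.0]))
        out = downsample(cube, 4)
        # src = (dst + 0.5) * 4 - 0.5; the ramp is linear so bilinear is exact
        d = np.arange(4)
        src = (d + 0.5) * 4 - 0.5
        expected = src[:, None] + src[None, :]
        np.testing.assert_allclose(out.data[:, :, 0], expected, atol=1e-9)

    def test_upsample_matches_continuous_interpolant(self, rng):
        """Upsampled values equal the continuous bilinear interpolant of the
        source evaluated at the mapped output coordinates."""
        src = rng.random((7, 5, 3))
        cube = Hypercube(src, WavelengthGrid([500.0, 600.0, 700.0]))
        out = upsample(cube, (21, 15))
        interp = RegularGridInterpolator(
            (np.arange(7), np.arange(5)), src, bounds_error=False, fill_value=None
        )
        ys = np.clip((np.arange(21) + 0.5) * (7 / 21) - 0.5, 0, 6)
        xs = np.clip((np.arange(15) + 0.5) * (5 / 15) - 0.5, 0, 4)
        pts = np.stack(np.meshgrid(ys, xs, indexing="ij"), axis=-1).reshape(-1, 2)
        expected = interp(pts).reshape(21, 15, 3)
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_upsample_constant_and_contract(self, small_grid):
        cube = _constant_cube(0.3, (112, 112, 31), small_grid)
        out = upsample(cube, (448, 448))
        assert out.shape == (448, 448, 31)
        np.testing.assert_allclose(out.data, 0.3, atol=1e-12)
        with pytest.raises(ValueError):
            upsample(cube, (56, 56))

    def test_up_down_identity_on_constant(self, small_grid):
        cube = _constant_cube(0.7, (8, 8, 31), small_grid)
        back = downsample(upsample(cube, (32, 32)), 4)
        np.testing.assert_allclose(back.data, cube.data, atol=1e-12)


class TestMakeLrHsi:
    def test_paper_scale_shapes(self):
        grid = WavelengthGrid.linear(400, 1000, 8)
        cube = Hypercube(np.random.default_rng(0).random((448, 448, 8),
                                                         dtype=np.float32), grid)
        lr = make_lr_hsi(cube, DegradationSpec())
        assert lr.shape == (112, 112, 8)
        assert len(lr.wavelengths) == 8          # spectral resolution preserved
        np.testing.assert_array_equal(lr.wavelengths.values, grid.values)

    def test_identity_spec(self, random_cube):
        spec = DegradationSpec(blur_kernel=1, down_factor=1)
        out = make_lr_hsi(random_cube, spec)
        np.testing.assert_array_equal(out.data, random_cube.data)

    def test_composition(self, phantom_sample):
        spec = DegradationSpec()
        lr = make_lr_hsi(phantom_sample.cube, spec)
        manual = downsample(gaussian_blur(phantom_sample.cube, 5, 10.0), 4)
        np.testing.assert_array_equal(lr.data, manual.data)


class TestExtractRgb:
    def test_nearest_bands(self, phantom_sample):
        rgb = extract_rgb(phantom_sample.cube)
        grid = phantom_sample.cube.wavelengths
        for ch, w in enumerate((650.0, 532.0, 473.0)):
            band = grid.nearest_index(w)
            np.testing.assert_array_equal(rgb.data[:, :, ch],
                                          phantom_sample.cube.data[:, :, band])

    def test_exact_grid_match(self, rng):
        grid = WavelengthGrid([473.0, 532.0, 650.0, 800.0])
        cube = Hypercube(rng.random((4, 4, 4)), grid)
        rgb = extract_rgb(cube)
        np.testing.assert_array_equal(rgb.data[:, :, 0], cube.data[:, :, 2])
        np.testing.assert_array_equal(rgb.data[:, :, 1], cube.data[:, :, 1])
        np.testing.assert_array_equal(rgb.data[:, :, 2], cube.data[:, :, 0])

    def test_out_of_range_errors(self, random_cube):
        with pytest.raises(ValueError):
            extract_rgb(random_cube, (650.0, 532.0, 300.0))


class TestBandNoise:
    def test_untouched_bands_bit_identical(self, random_cube):
        out = add_band_noise(random_cube, 0.01, (980.0, 1000.0), seed=1)
        grid = random_cube.wavelengths
        below = grid.values < 980.0
        np.testing.assert_array_equal(out.data[:, :, below],
                                      random_cube.data[:, :, below])
        changed = grid.values >= 980.0
        assert not np.array_equal(out.data[:, :, changed],
                                  random_cube.data[:, :, changed])

    def test_zero_variance_identity(self, random_cube):
        out = add_band_noise(random_cube, 0.0, (980.0, 1000.0), seed=1)
        np.testing.assert_array_equal(out.data, random_cube.data)

    @pytest.mark.parametrize("variance", [0.01, 0.07])
    def test_empirical_variance(self, variance):
        grid = WavelengthGrid.linear(400, 1000, 31)
        cube = Hypercube(np.full((256, 256, 31), 0.5), grid)
        out = add_band_noise(cube, variance, (980.0, 1000.0), seed=3)
        bands = grid.indices_in_range(980.0, 1000.0)
        resid = out.data[:, :, bands] - 0.5
        assert resid.size >= 1e5
        assert abs(resid.var() / variance - 1.0) < 0.05
        assert abs(resid.mean()) < 0.01          # zero-mean

    def test_deterministic_in_seed(self, random_cube):
        a = add_band_noise(random_cube, 0.03, (980.0, 1000.0), seed=5)
        b = add_band_noise(random_cube, 0.03, (980.0, 1000.0), seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_empty_band_range_errors(self, random_cube):
        with pytest.raises(ValueError):
            add_band_noise(random_cube, 0.01, (1500.0, 1600.0), seed=0)


class TestDeadPixels:
    def test_listed_coords_zeroed(self, phantom_sample):
        coords = [(r, c) for r, c in np.argwhere(phantom_sample.labels > 0)[:12]]
        out, used = inject_dead_pixels(phantom_sample.cube, coords=coords)
        assert used == [tuple(c) for c in coords]
        for r, c in coords:
            assert np.all(out.data[r, c, :] == 0.0)
        untouched = np.ones(out.shape[:2], dtype=bool)
        for r, c in coords:
            untouched[r, c] = False
        np.testing.assert_array_equal(out.data[untouched],
                                      phantom_sample.cube.data[untouched])

    def test_empty_coords_identity(self, random_cube):
        out, used = inject_dead_pixels(random_cube, coords=[])
        assert used == []
        np.testing.assert_array_equal(out.data, random_cube.data)

    def test_rate_counts_foreground(self, small_grid):
        cube = Hypercube(np.full((100, 100, 31), 0.5, dtype=np.float32), small_grid)
        out, used = inject_dead_pixels(cube, rate=0.01, seed=2)
        assert len(used) == 100
        zeroed = np.all(out.data == 0.0, axis=2)
        assert zeroed.sum() == 100

    def test_out_of_bounds_errors(self, random_cube):
        with pytest.raises(ValueError):
            inject_dead_pixels(random_cube, coords=[(99, 0)])


class TestSpecular:
    def test_region_pixel_counts(self, phantom_sample):
        regions = [(4, 4, 2), (10, 10, 3), (20, 20, 4), (30, 30, 5)]
        out = inject_specular(phantom_sample.cube, regions, plateau=1.2)
        grid = phantom_sample.cube.wavelengths
        bands = grid.indices_in_range(675.0, 705.0)
        saturated = np.any(out.data[:, :, bands] > 1.0, axis=2)
        assert saturated.sum() == 4 + 9 + 16 + 25

    def test_bands_outside_window_untouched(self, phantom_sample):
        out = inject_specular(phantom_sample.cube, [(4, 4, 3)], plateau=1.2)
        grid = phantom_sample.cube.wavelengths
        outside = np.setdiff1d(np.arange(31), grid.indices_in_range(675.0, 705.0))
        np.testing.assert_array_equal(out.data[:, :, outside],
                                      phantom_sample.cube.data[:, :, outside])
        inside = grid.indices_in_range(675.0, 705.0)
        assert np.all(out.data[4:7, 4:7][:, :, inside] == np.float32(1.2))

    def test_empty_regions_identity(self, random_cube):
        out = inject_specular(random_cube, [])
        np.testing.assert_array_equal(out.data, random_cube.data)

    def test_overlap_rejected(self, phantom_sample):
        with pytest.raises(ValueError, match="overlap"):
            inject_specular(phantom_sample.cube, [(4, 4, 3), (5, 5, 3)])

    def test_plateau_must_exceed_one(self, random_cube):
        with pytest.raises(ValueError):
            inject_specular(random_cube, [(0, 0, 2)], plateau=0.9)


def test_degradation_spec_validation():
    with pytest.raises(ValueError):
        DegradationSpec(blur_kernel=4)
    with pytest.raises(ValueError):
        DegradationSpec(dead_pixel_rate=0.2)
    with pytest.raises(ValueError):
        DegradationSpec(plateau_value=1.0)
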