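"""Quality metrics against naive-loop oracles and closed forms."""

import math

import numpy as np
import pytest

from lumifuse import Hypercube, WavelengthGrid, ergas, evaluate_pair, psnr, rmse, sam


# ---------------------------------------------------------------------------
# Independent naive-loop oracles (no vectorization, no shared code paths)
# ---------------------------------------------------------------------------

def rmse_oracle(g, r, mask):
    total, n = 0.0, 0
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            if mask[i, j]:
                for k in range(g.shape[2]):
                    total += (float(g[i, j, k]) - float(r[i, j, k])) ** 2
                    n += 1
    return math.sqrt(total / n)


def psnr_oracle(g, r, mask):
    per_band = []
    for k in range(g.shape[2]):
        peak, sse, n = 0.0, 0.0, 0
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                if mask[i, j]:
                    peak = max(peak, float(g[i, j, k]))
                    sse += (float(g[i, j, k]) - float(r[i, j, k])) ** 2
                    n += 1
        mse = sse / n
        per_band.append(float("inf") if mse == 0 else 10 * math.log10(peak**2 / mse))
    finite = [p for p in per_band if math.isfinite(p)]
    return per_band, sum(finite) / len(finite)


def ergas_oracle(g, r, mask, ratio):
    z = g.shape[2]
    acc = 0.0
    for k in range(g.shape[2]):
        sse, su, n = 0.0, 0.0, 0
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                if mask[i, j]:
                    sse += (float(g[i, j, k]) - float(r[i, j, k])) ** 2
                    su += float(g[i, j, k])
                    n += 1
        acc += (math.sqrt(sse / n) / (su / n)) ** 2
    return 100.0 * ratio * math.sqrt(acc / z)


def sam_oracle(g, r, mask):
    angles = []
    skipped = 0
    for i in range(g.shape[0]):
        for j in range(g.shape[1]):
            if mask[i, j]:
                a = g[i, j, :].astype(float)
                b = r[i, j, :].astype(float)
                na, nb = math.sqrt(float(a @ a)), math.sqrt(float(b @ b))
                if na == 0 or nb == 0:
                    skipped += 1
                    continue
                c = min(1.0, max(-1.0, float(a @ b) / (na * nb)))
                angles.append(math.degrees(math.acos(c)))
    return sum(angles) / len(angles), skipped


def _random_pair(rng):
    g = rng.random((8, 8, 5)) + 0.05
    r = g + rng.normal(0, 0.05, g.shape)
    mask = rng.random((8, 8)) > 0.3
    if not mask.any():
        mask[0, 0] = True
    return g, np.abs(r), mask


def test_vectorized_metrics_match_loop_oracles(rng):
    """All four metrics agree with brute-force loops on 20 random pairs."""
    for _ in range(20):
        g, r, mask = _random_pair(rng)
        assert abs(rmse(g, r, mask) - rmse_oracle(g, r, mask)) < 1e-12
        pb, mean = psnr(g, r, mask)
        pb_o, mean_o = psnr_oracle(g, r, mask)
        np.testing.assert_allclose(pb, pb_o, atol=1e-10)
        assert abs(mean - mean_o) < 1e-10
        assert abs(ergas(g, r, mask, 1.0) - ergas_oracle(g, r, mask, 1.0)) < 1e-10
        s, k = sam(g, r, mask)
        s_o, k_o = sam_oracle(g, r, mask)
        assert abs(s - s_o) < 1e-10 and k == k_o


class TestClosedForms:
    mask3 = np.ones((3, 3), dtype=bool)

    def test_rmse_constant_offset(self):
        g = np.full((3, 3, 2), 1.0)
        r = np.full((3, 3, 2), 0.9)
        assert abs(rmse(g, r, self.mask3) - 0.1) < 1e-12
        assert rmse(g, g, self.mask3) == 0.0

    def test_psnr_constant_offset_is_20db(self):
        g = np.full((3, 3, 1), 1.0)
        r = np.full((3, 3, 1), 0.9)
        pb, mean = psnr(g, r, self.mask3)
        assert abs(mean - 20.0) < 1e-10           # 10 log10(1 / 0.01)

    def test_psnr_identical_inf_excluded(self):
        g = np.stack([np.full((3, 3), 1.0), np.full((3, 3), 0.5)], axis=2)
        r = g.copy()
        r[:, :, 1] = 0.4
        pb, mean = psnr(g, r, self.mask3)
        assert np.isinf(pb[0])
        assert np.isfinite(mean)                  # band 0 excluded from mean

    def test_ergas_single_band(self):
        g = np.full((4, 4, 1), 0.5)
        r = g - 0.05
        assert abs(ergas(g, r, np.ones((4, 4), bool), 1.0) - 10.0) < 1e-10
        assert ergas(g, g, np.ones((4, 4), bool), 1.0) == 0.0

    def test_ergas_scales_with_ratio(self):
        g = np.full((4, 4, 1), 0.5)
        r = g - 0.05
        m = np.ones((4, 4), bool)
        assert abs(ergas(g, r, m, 0.25) - 2.5) < 1e-10

    def test_sam_closed_form_angles(self):
        m = np.ones((1, 1), bool)
        s, _ = sam(np.array([[[1.0, 0.0]]]), np.array([[[0.0, 1.0]]]), m)
        assert abs(s - 90.0) < 1e-10
        s, _ = sam(np.array([[[1.0, 0.0]]]), np.array([[[1.0, 1.0]]]), m)
        assert abs(s - 45.0) < 1e-10
        s, _ = sam(np.array([[[0.3, 0.7]]]), np.array([[[0.3, 0.7]]]), m)
        assert s == 0.0


class TestInvariances:
    def test_sam_scale_invariant(self, rng):
        g, r, mask = _random_pair(rng)
        scale = rng.uniform(0.5, 2.0, size=(8, 8, 1))
        s1, _ = sam(g, r, mask)
        s2, _ = sam(g, r * scale, mask)
        s3, _ = sam(g * scale, r, mask)
        assert abs(s1 - s2) < 1e-9 and abs(s1 - s3) < 1e-9

    def test_rmse_linear_ergas_invariant_under_global_scale(self, rng):
        g, r, mask = _random_pair(rng)
        c = 3.7
        assert abs(rmse(g * c, r * c, mask) - c * rmse(g, r, mask)) < 1e-10
        assert abs(ergas(g * c, r * c, mask, 1.0) - ergas(g, r, mask, 1.0)) < 1e-9

    def test_psnr_decreases_with_noise(self, rng):
        g = rng.random((16, 16, 4)) + 0.1
        mask = np.ones((16, 16), bool)
        means = []
        for sd in (0.01, 0.05, 0.1, 0.2):
            noise = np.random.default_rng(99).normal(0, sd, g.shape)
            means.append(psnr(g, g + noise, mask)[1])
        assert all(a > b for a, b in zip(means, means[1:]))


class TestContracts:
    def test_empty_mask_errors(self, rng):
        g = rng.random((4, 4, 2))
        with pytest.raises(ValueError):
            rmse(g, g, np.zeros((4, 4), bool))

    def test_shape_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            rmse(rng.random((4, 4, 2)), rng.random((4, 4, 3)), np.ones((4, 4), bool))

    def test_zero_peak_band_errors(self):
        g = np.zeros((3, 3, 1))
        with pytest.raises(ValueError, match="band 0"):
            psnr(g, g, np.ones((3, 3), bool))

    def test_all_zero_spectra_skipped_errors(self):
        g = np.zeros((2, 2, 3))
        with pytest.raises(ValueError):
            sam(g, g, np.ones((2, 2), bool))


class TestEvaluatePair:
    def test_identical_pair(self, phantom_sample):
        report = evaluate_pair(phantom_sample.cube, phantom_sample.cube.data)
        assert report.rmse == 0.0 and report.ergas == 0.0
        assert report.sam < 1e-6      # arccos rounding on float32 spectra
        assert report.n_psnr_excluded == len(phantom_sample.cube.wavelengths)

    def test_fields_match_individual_metrics(self, rng, small_grid):
        g = rng.random((8, 8, 31)) + 0.05
        r = g + rng.normal(0, 0.02, g.shape)
        cube = Hypercube(g, small_grid)
        mask = np.ones((8, 8), bool)
        report = evaluate_pair(cube, r, mask, ratio=0.25)
        assert report.rmse == rmse(g, r, mask)
        assert report.psnr == psnr(g, r, mask)[1]
        assert report.ergas == ergas(g, r, mask, 0.25)
        assert report.sam == sam(g, r, mask)[0]
        assert report.n_pixels_used == 64

    def test_mask_excludes_background_disagreement(self, small_grid):
        g = np.zeros((6, 6, 31))
        g[2:4, 2:4, :] = 0.5                  # foreground block
        r = g.copy()
        r[0, 0, :] = 0.9                      # background-only disagreement
        cube = Hypercube(g, small_grid)
        masked = evaluate_pair(cube, r)       # mask from reference
        assert masked.rmse == 0.0
        unmasked = rmse(g, r, np.ones((6, 6), bool))
        assert unmasked > 0.0
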