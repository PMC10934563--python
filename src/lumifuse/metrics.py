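"""Background-masked full-reference quality metrics: RMSE, PSNR, ERGAS, SAM.

All metrics exclude black background pixels: a boolean foreground mask
(normally derived from the *reference* cube) restricts every sum to tissue
pixels, so a large background cannot bias the scores.  Conventions:

* RMSE — root mean square reflectance error over masked pixels and all bands.
* PSNR — per band ``10 log10(max(G_k)^2 / MSE_k)`` with the max taken over
  masked reference pixels, averaged over bands (dB).  A band reproduced
  exactly has infinite PSNR; such bands are excluded from the mean and their
  count reported.
* ERGAS — ``100 * ratio * sqrt(mean_k (RMSE_k / mu_k)^2)`` where ``mu_k`` is
  the masked reference band mean.  ``ratio`` defaults to 1 (estimate and
  reference at the same spatial resolution); pass ``1/down_factor`` when
  scoring a low-resolution product against a high-resolution reference.
* SAM — mean per-pixel angle (degrees) between estimate and reference
  spectra; pixels where either spectrum has zero norm are skipped and
  counted.  Invariant to positive per-pixel scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypercube import BackgroundMask, Hypercube

__all__ = ["MetricsReport", "rmse", "psnr", "ergas", "sam", "evaluate_pair"]


def _as_array(cube) -> np.ndarray:
    return cube.data if isinstance(cube, Hypercube) else np.asarray(cube)


def _as_mask(mask, shape) -> np.ndarray:
    m = mask.data if isinstance(mask, BackgroundMask) else np.asarray(mask, dtype=bool)
    if m.shape != shape[:2]:
        raise ValueError(f"mask shape {m.shape} does not match spatial shape {shape[:2]}")
    if not m.any():
        raise ValueError("mask has no foreground pixels")
    return m


def _check_shapes(g: np.ndarray, r: np.ndarray) -> None:
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: reference {g.shape} vs estimate {r.shape}")


@dataclass
class MetricsReport:
    """Bundle of the four masked metrics for one (estimate, reference) pair."""

    rmse: float
    psnr_per_band: np.ndarray
    psnr: float
    ergas: float
    sam: float
    ratio: float
    n_pixels_used: int
    n_sam_skipped: int
    n_psnr_excluded: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "psnr": self.psnr,
            "ergas": self.ergas,
            "sam": self.sam,
            "ratio": self.ratio,
            "n_pixels_used": self.n_pixels_used,
            "n_sam_skipped": self.n_sam_skipped,
            "n_psnr_excluded": self.n_psnr_excluded,
        }


def rmse(reference, estimate, mask) -> float:
    """Masked root mean square error over all pixels and bands."""
    g, r = _as_array(reference), _as_array(estimate)
    _check_shapes(g, r)
    m = _as_mask(mask, g.shape)
    diff = (g[m].astype(np.float64) - r[m].astype(np.float64)) ** 2
    return float(np.sqrt(diff.mean()))


def psnr(reference, estimate, mask) -> tuple[np.ndarray, float]:
    """Masked per-band PSNR (dB) and its mean over bands.

    Bands with zero error are +inf and excluded from the mean.  A band whose
    masked reference maximum is zero has an undefined peak and raises.
    """
    g, r = _as_array(reference), _as_array(estimate)
    _check_shapes(g, r)
    m = _as_mask(mask, g.shape)
    gm = g[m].astype(np.float64)            # (n_fg, Z)
    rm = r[m].astype(np.float64)
    peak = gm.max(axis=0)
    zero_peak = np.nonzero(peak <= 0)[0]
    if zero_peak.size:
        raise ValueError(f"band {int(zero_peak[0])} has zero masked reference maximum")
    mse = ((gm - rm) ** 2).mean(axis=0)
    with np.errstate(divide="ignore"):
        per_band = 10.0 * np.log10(peak**2 / mse)
    finite = np.isfinite(per_band)
    mean = float(per_band[finite].mean()) if finite.any() else float("inf")
    return per_band, mean


def ergas(reference, estimate, mask, ratio: float = 1.0) -> float:
    """Masked relative dimensionless global error (percent-scaled)."""
    g, r = _as_array(reference), _as_array(estimate)
    _check_shapes(g, r)
    m = _as_mask(mask, g.shape)
    gm = g[m].astype(np.float64)
    rm = r[m].astype(np.float64)
    mu = gm.mean(axis=0)
    zero_mu = np.nonzero(mu <= 0)[0]
    if zero_mu.size:
        raise ValueError(f"band {int(zero_mu[0])} has zero masked reference mean")
    band_rmse = np.sqrt(((gm - rm) ** 2).mean(axis=0))
    return float(100.0 * ratio * np.sqrt(((band_rmse / mu) ** 2).mean()))


def sam(reference, estimate, mask) -> tuple[float, int]:
    """Masked mean spectral angle (degrees) and the count of skipped pixels.

    Pixels where either spectrum has zero norm carry no angular information
    and are skipped (and counted); the arccos argument is clamped to [-1, 1].
    """
    g, r = _as_array(reference), _as_array(estimate)
    _check_shapes(g, r)
    m = _as_mask(mask, g.shape)
    gm = g[m].astype(np.float64)
    rm = r[m].astype(np.float64)
    ng = np.linalg.norm(gm, axis=1)
    nr = np.linalg.norm(rm, axis=1)
    valid = (ng > 0) & (nr > 0)
    skipped = int((~valid).sum())
    if not valid.any():
        raise ValueError("all masked pixels have a zero-norm spectrum")
    cosang = (gm[valid] * rm[valid]).sum(axis=1) / (ng[valid] * nr[valid])
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(angles.mean()), skipped


def evaluate_pair(reference, estimate, mask=None, ratio: float = 1.0) -> MetricsReport:
    """All four masked metrics in one report.

    If ``mask`` is None it is derived from the reference cube with the
    default foreground threshold.
    """
    if mask is None:
        from .hypercube import compute_background_mask

        if not isinstance(reference, Hypercube):
            raise ValueError("pass a mask explicitly when reference is a bare array")
        mask = compute_background_mask(reference)
    g = _as_array(reference)
    m = _as_mask(mask, g.shape)
    per_band, psnr_mean = psnr(reference, estimate, m)
    sam_mean, sam_skipped = sam(reference, estimate, m)
    return MetricsReport(
        rmse=rmse(reference, estimate, m),
        psnr_per_band=per_band,
        psnr=psnr_mean,
        ergas=ergas(reference, estimate, m, ratio),
        sam=sam_mean,
        ratio=float(ratio),
        n_pixels_used=int(m.sum()),
        n_sam_skipped=sam_skipped,
        n_psnr_excluded=int(np.sum(~np.isfinite(per_band))),
    )
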