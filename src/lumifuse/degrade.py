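"""Forward degradation models: snapshot/RGB simulation and corruption injectors.

A high-resolution reference cube (HR-HSI) is turned into the two network
inputs:

* LR-HSI — per-band Gaussian blur (anti-aliasing, default 5x5 kernel, sd 10 px)
  followed by bilinear downsampling (default factor 4).  All bands are kept:
  only spatial resolution is reduced, emulating a snapshot camera.
* HR-RGB — the three reference bands nearest 650/532/473 nm at full spatial
  resolution, emulating a regular color camera (no blur).

Four corruption injectors emulate common sensor/scene problems; they are
applied to the LR-HSI (a color camera with a polarization filter is assumed
clean):

* extra Gaussian blur (motion artifacts, kernels 5-35),
* zero-mean uniform noise in a wavelength window (reduced sensor sensitivity
  at the spectral extremities, default 980-1000 nm),
* dead pixels — whole spectra set to exactly 0,
* specular-saturation plateaus >1 inside small squares, confined to a
  wavelength window (default 675-705 nm).

Noise is never clipped, so the requested variance is preserved exactly (noisy
bands may dip below 0, as real calibrated spectra do).  Every stochastic
operation is a pure function of (input, parameters, seed).

Resampling convention: bilinear, output pixel center ``dst`` maps to source
coordinate ``src = (dst + 0.5) * scale - 0.5`` (the align-corners=False
convention), coordinates clamped at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hypercube import Hypercube, RGBImage, compute_background_mask

__all__ = [
    "DegradationSpec",
    "gaussian_kernel_1d",
    "gaussian_blur",
    "downsample",
    "upsample",
    "make_lr_hsi",
    "extract_rgb",
    "add_band_noise",
    "inject_dead_pixels",
    "inject_specular",
]


@dataclass(frozen=True)
class DegradationSpec:
    """Full parameterization of the forward model and the four injectors."""

    blur_kernel: int = 5
    blur_sd: float = 10.0
    down_factor: int = 4
    rgb_wavelengths: tuple[float, float, float] = (650.0, 532.0, 473.0)
    noise_variance: float = 0.0
    noise_band_range: tuple[float, float] = (980.0, 1000.0)
    dead_pixel_coords: tuple[tuple[int, int], ...] | None = None
    dead_pixel_rate: float = 0.0
    specular_regions: tuple[tuple[int, int, int], ...] = ()
    specular_band_range: tuple[float, float] = (675.0, 705.0)
    plateau_value: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError("blur_kernel must be odd and >= 1")
        if self.down_factor < 1:
            raise ValueError("down_factor must be >= 1")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if not (0.0 <= self.dead_pixel_rate <= 0.05):
            raise ValueError("dead_pixel_rate must be in [0, 0.05]")
        if self.plateau_value <= 1.0:
            raise ValueError("plateau_value must exceed 1 (saturation)")


def gaussian_kernel_1d(size: int, sd: float) -> np.ndarray:
    """Truncated discrete Gaussian: sampled at integer offsets, sum 1."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sd) ** 2) if sd > 0 else (x == 0).astype(np.float64)
    return k / k.sum()


def gaussian_blur(cube: Hypercube, kernel: int, sd: float) -> Hypercube:
    """Per-band 2-D Gaussian blur, reflect (symmetric) padding, shape unchanged."""
    rows, cols, _ = cube.shape
    if kernel % 2 == 0:
        raise ValueError("blur kernel must be odd")
    if kernel > min(rows, cols):
        raise ValueError(f"kernel {kernel} exceeds spatial extent {rows}x{cols}")
    if kernel == 1:
        return cube.with_data(cube.data.copy())
    k = gaussian_kernel_1d(kernel, sd)
    out = ndimage.correlate1d(cube.data, k, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, k, axis=1, mode="reflect")
    return cube.with_data(out)


def _resize_bilinear(data: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize of a (H, W, C) array at output pixel centers."""
    in_h, in_w = data.shape[:2]

    def coords(n_out: int, n_in: int):
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        i0 = np.floor(src).astype(np.intp)
        i1 = np.minimum(i0 + 1, n_in - 1)
        return i0, i1, src - i0

    r0, r1, fr = coords(out_h, in_h)
    c0, c1, fc = coords(out_w, in_w)
    fr = fr[:, None, None]
    fc = fc[None, :, None]
    rows = data[r0] * (1.0 - fr) + data[r1] * fr
    return rows[:, c0] * (1.0 - fc) + rows[:, c1] * fc


def downsample(cube: Hypercube, factor: int) -> Hypercube:
    """Bilinear downsampling by an integer factor; dims must divide evenly."""
    rows, cols, _ = cube.shape
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if rows % factor or cols % factor:
        raise ValueError(
            f"spatial dims {rows}x{cols} not divisible by factor {factor}; crop first"
        )
    if factor == 1:
        return cube.with_data(cube.data.copy())
    return cube.with_data(_resize_bilinear(cube.data, rows // factor, cols // factor))


def upsample(cube: Hypercube, target_hw: tuple[int, int]) -> Hypercube:
    """Bilinear upsampling to ``(target_h, target_w)``; same center mapping."""
    rows, cols, _ = cube.shape
    th, tw = target_hw
    if th < rows or tw < cols:
        raise ValueError(f"target {th}x{tw} smaller than input {rows}x{cols}")
    if (th, tw) == (rows, cols):
        return cube.with_data(cube.data.copy())
    return cube.with_data(_resize_bilinear(cube.data, th, tw))


def make_lr_hsi(reference: Hypercube, spec: DegradationSpec) -> Hypercube:
    """LR-HSI = Gaussian blur then bilinear downsample; all bands retained."""
    blurred = gaussian_blur(reference, spec.blur_kernel, spec.blur_sd)
    return downsample(blurred, spec.down_factor)


def extract_rgb(
    reference: Hypercube,
    wavelengths: tuple[float, float, float] = (650.0, 532.0, 473.0),
) -> RGBImage:
    """HR-RGB = the reference bands nearest the requested wavelengths (R, G, B)."""
    idx = [reference.wavelengths.nearest_index(float(w)) for w in wavelengths]
    return RGBImage(reference.data[:, :, idx].copy(), tuple(float(w) for w in wavelengths))


def add_band_noise(
    cube: Hypercube,
    variance: float,
    band_range: tuple[float, float] = (980.0, 1000.0),
    seed: int = 0,
) -> Hypercube:
    """Zero-mean uniform noise of the given variance in a wavelength window.

    Uniform on [-sqrt(3 v), +sqrt(3 v)], i.i.d. per affected entry; bands
    outside the window are bit-unchanged; no clipping.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    bands = cube.wavelengths.indices_in_range(*band_range)
    if bands.size == 0:
        raise ValueError(f"no bands fall inside {band_range} nm")
    if variance == 0:
        return cube.with_data(cube.data.copy())
    rng = np.random.default_rng(seed)
    half_width = float(np.sqrt(3.0 * variance))
    out = cube.data.copy()
    noise = rng.uniform(-half_width, half_width,
                        size=(out.shape[0], out.shape[1], bands.size))
    out[:, :, bands] = out[:, :, bands] + noise.astype(out.dtype, copy=False)
    return cube.with_data(out)


def inject_dead_pixels(
    cube: Hypercube,
    coords: list[tuple[int, int]] | None = None,
    rate: float | None = None,
    seed: int = 0,
) -> tuple[Hypercube, list[tuple[int, int]]]:
    """Zero whole spectra at given coordinates, or at a foreground fraction.

    With ``rate``, ``round(rate * n_foreground)`` pixels are drawn uniformly
    over foreground positions (background zeros would be invisible to masked
    metrics).  Returns the corrupted cube and the coordinates used.
    """
    rows, cols, _ = cube.shape
    if coords is None:
        if rate is None:
            raise ValueError("pass either coords or rate")
        if not (0.0 <= rate <= 0.05):
            raise ValueError("rate must be in [0, 0.05]")
        mask = compute_background_mask(cube).data
        fg = np.argwhere(mask)
        n = int(round(rate * len(fg)))
        rng = np.random.default_rng(seed)
        chosen = fg[rng.choice(len(fg), size=n, replace=False)] if n else fg[:0]
        coords = [tuple(int(v) for v in rc) for rc in chosen]
    else:
        for r, c in coords:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"dead pixel ({r}, {c}) out of bounds {rows}x{cols}")
        coords = [(int(r), int(c)) for r, c in coords]
    out = cube.data.copy()
    for r, c in coords:
        out[r, c, :] = 0.0
    return cube.with_data(out), coords


def inject_specular(
    cube: Hypercube,
    regions: list[tuple[int, int, int]],
    band_range: tuple[float, float] = (675.0, 705.0),
    plateau: float = 1.2,
) -> Hypercube:
    """Saturation plateaus: squares set to ``plateau`` inside a wavelength window.

    Each ``(row, col, size)`` square is anchored at its top-left corner.
    Regions must lie in bounds and must not overlap (keeps per-region pixel
    counts interpretable).  Bands outside the window are bit-unchanged.
    """
    if plateau <= 1.0:
        raise ValueError("plateau must exceed 1 (saturation)")
    rows, cols, _ = cube.shape
    bands = cube.wavelengths.indices_in_range(*band_range)
    if bands.size == 0:
        raise ValueError(f"no bands fall inside {band_range} nm")
    occupied = np.zeros((rows, cols), dtype=bool)
    out = cube.data.copy()
    for r, c, size in regions:
        if size < 1:
            raise ValueError("region size must be >= 1")
        if not (0 <= r and r + size <= rows and 0 <= c and c + size <= cols):
            raise ValueError(f"region ({r}, {c}, {size}) out of bounds {rows}x{cols}")
        block = occupied[r:r + size, c:c + size]
        if block.any():
            raise ValueError(f"region ({r}, {c}, {size}) overlaps a previous region")
        block[:] = True
        sub = out[r:r + size, c:c + size, :]
        sub[:, :, bands] = plateau
    return cube.with_data(out)
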