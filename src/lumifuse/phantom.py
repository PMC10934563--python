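"""Synthetic lumpectomy-like phantom generator.

The clinical reflectance hypercubes this package targets — resection specimens
imaged on a black background with a line-scanning camera — are not publicly
distributable, so every pipeline stage trains and tests on phantoms that
emulate their gross structure:

* an elliptical specimen on an exactly-zero black background,
* 2-4 spectrally distinct, spatially smooth tissue regions inside the ellipse,
* per-class endmember spectra that are smooth over wavelength (sums of positive
  Gaussian bumps plus a linear baseline, rescaled into [0.1, 0.9]),
* a spatially smooth multiplicative texture field within each class,
* optional extra sensor noise in the spectral extremities (the lowest/highest
  ~50 nm of the grid), mimicking reduced sensor sensitivity there.

Everything is a pure function of the spec and its seed: the same
``PhantomSpec`` always produces the bit-identical cube.  The generator makes
no attempt at biophysically accurate breast-tissue optics; it provides
controlled spectral/spatial contrast for reconstruction experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hypercube import Hypercube, WavelengthGrid

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_cohort",
    "derive_seed",
    "edge_band_indices",
]

#: Minimum pairwise spectral angle (degrees) between class endmembers.
MIN_ENDMEMBER_ANGLE_DEG = 5.0

#: Width of the "spectral extremity" windows at both ends of the grid (nm).
EDGE_WINDOW_NM = 50.0


def derive_seed(*keys: int) -> int:
    """Deterministic sub-seed (< 2**31) from a tuple of integer keys."""
    ss = np.random.SeedSequence(list(keys))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic specimen cube.

    ``spectrum_smoothness`` is the characteristic width (nm) of the Gaussian
    bumps composing the endmember spectra; ``spatial_texture_sd`` is the
    relative within-class reflectance variation; ``edge_noise_sd`` is the
    additive noise amplitude applied in the lowest/highest ~50 nm of the grid.
    """

    height: int
    width: int
    n_bands: int = 384
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    n_tissue_classes: int = 3
    ellipse_fill_fraction: float = 0.5
    spectrum_smoothness: float = 60.0
    spatial_texture_sd: float = 0.05
    edge_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 4:
            raise ValueError("n_bands must be at least 4")
        if self.n_tissue_classes < 1:
            raise ValueError("need at least one tissue class")
        if not (0.0 < self.ellipse_fill_fraction < 1.0):
            raise ValueError("ellipse_fill_fraction must be in (0, 1)")
        if min(self.spatial_texture_sd, self.edge_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.height < 4 or self.width < 4:
            raise ValueError("phantom must be at least 4x4 pixels")

    @property
    def grid(self) -> WavelengthGrid:
        lo, hi = self.wavelength_range
        return WavelengthGrid.linear(lo, hi, self.n_bands)


@dataclass
class PhantomSample:
    """A phantom cube plus its ground truth: label map and class endmembers."""

    cube: Hypercube
    labels: np.ndarray          # (Y, X) int, 0 = background, 1..n = classes
    endmembers: np.ndarray      # (n_classes, Z) spectra over the grid

    @property
    def patient_id(self) -> str | None:
        return self.cube.patient_id


def _spectral_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _draw_endmember(rng: np.random.Generator, wl: np.ndarray, smoothness: float) -> np.ndarray:
    lo, hi = wl[0], wl[-1]
    n_bumps = int(rng.integers(2, 5))
    spectrum = np.zeros_like(wl)
    for _ in range(n_bumps):
        center = rng.uniform(lo, hi)
        width = rng.uniform(0.5, 2.0) * smoothness
        amp = rng.uniform(0.3, 1.0)
        spectrum += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    slope = rng.uniform(-0.3, 0.3)
    spectrum += slope * (wl - lo) / (hi - lo)
    # Affine rescale into [0.1, 0.9]: keeps reflectance well inside [0, 1] so
    # small texture/noise perturbations survive the final clip untouched.
    smin, smax = spectrum.min(), spectrum.max()
    if smax - smin < 1e-9:
        spectrum = np.full_like(wl, 0.5)
    else:
        spectrum = 0.1 + 0.8 * (spectrum - smin) / (smax - smin)
    return spectrum


def _draw_endmembers(rng: np.random.Generator, wl: np.ndarray, n_classes: int,
                     smoothness: float) -> np.ndarray:
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_classes:
        candidate = _draw_endmember(rng, wl, smoothness)
        if all(_spectral_angle_deg(candidate, e) >= MIN_ENDMEMBER_ANGLE_DEG
               for e in accepted):
            accepted.append(candidate)
        attempts += 1
        if attempts > 200 * n_classes:
            raise RuntimeError(
                "could not draw spectrally distinct endmembers "
                f"(pairwise angle >= {MIN_ENDMEMBER_ANGLE_DEG} deg)"
            )
    return np.stack(accepted)


def _ellipse_mask(rng: np.random.Generator, height: int, width: int,
                  fill_fraction: float) -> np.ndarray:
    area = fill_fraction * height * width
    ab = area / np.pi                       # product of semi-axes
    aspect = rng.uniform(0.6, 1.0)
    b = np.sqrt(ab * aspect)
    a = ab / b
    theta = rng.uniform(0.0, np.pi)
    cy = height / 2 + rng.uniform(-0.05, 0.05) * height
    cx = width / 2 + rng.uniform(-0.05, 0.05) * width
    rows, cols = np.mgrid[0:height, 0:width]
    dr, dc = rows + 0.5 - cy, cols + 0.5 - cx
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def edge_band_indices(grid: WavelengthGrid, window_nm: float = EDGE_WINDOW_NM) -> np.ndarray:
    """Band indices within ``window_nm`` of either end of the grid (exclusive bounds)."""
    lo, hi = grid.range
    wl = grid.values
    return np.nonzero((wl < lo + window_nm) | (wl > hi - window_nm))[0]


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one specimen phantom; bit-deterministic in ``spec.seed``.

    The cube is exactly zero at background pixels before the optional
    edge-band noise, and clipped to [0, 1] after it.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    wl = grid.values

    ellipse = _ellipse_mask(rng, spec.height, spec.width, spec.ellipse_fill_fraction)
    n_fg = int(ellipse.sum())
    if n_fg < spec.n_tissue_classes:
        raise ValueError(
            f"ellipse ({n_fg} px) too small to contain {spec.n_tissue_classes} classes"
        )

    # Smooth random fields; argmax carves the ellipse into blob-shaped regions.
    sigma = min(spec.height, spec.width) / 6.0
    fields = np.stack([
        ndimage.gaussian_filter(rng.standard_normal((spec.height, spec.width)), sigma)
        for _ in range(spec.n_tissue_classes)
    ])
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    labels[ellipse] = np.argmax(fields, axis=0)[ellipse] + 1

    endmembers = _draw_endmembers(rng, wl, spec.n_tissue_classes, spec.spectrum_smoothness)

    # Multiplicative within-class texture: 1 + sd * smooth unit-variance field.
    texture = np.ones((spec.height, spec.width))
    if spec.spatial_texture_sd > 0:
        f = ndimage.gaussian_filter(
            rng.standard_normal((spec.height, spec.width)),
            min(spec.height, spec.width) / 10.0,
        )
        f = (f - f.mean()) / max(f.std(), 1e-12)
        texture = np.clip(1.0 + spec.spatial_texture_sd * f, 0.0, None)

    cube = np.zeros((spec.height, spec.width, spec.n_bands), dtype=np.float32)
    for c in range(1, spec.n_tissue_classes + 1):
        where = labels == c
        if where.any():
            cube[where] = (texture[where, None] * endmembers[c - 1][None, :]).astype(np.float32)

    if spec.edge_noise_sd > 0:
        edge = edge_band_indices(grid)
        if edge.size:
            noise = rng.normal(0.0, spec.edge_noise_sd,
                               size=(spec.height, spec.width, edge.size))
            cube[:, :, edge] += noise.astype(np.float32)

    np.clip(cube, 0.0, 1.0, out=cube)

    hc = Hypercube(cube, grid, name=f"phantom-{spec.seed}")
    return PhantomSample(cube=hc, labels=labels, endmembers=endmembers)


def generate_cohort(spec: PhantomSpec, n_patients: int,
                    images_per_patient: int = 1) -> list[PhantomSample]:
    """Deterministic multi-patient cohort.

    Each sample's seed derives from ``(spec.seed, patient, image)``, so the
    cohort is reproducible independent of generation order, and every patient
    gets a distinct ``patient_id``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be at least 1")
    if images_per_patient < 1:
        raise ValueError("images_per_patient must be at least 1")
    cohort: list[PhantomSample] = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        for i in range(images_per_patient):
            sub = dataclasses.replace(spec, seed=derive_seed(spec.seed, p, i))
            sample = generate_phantom(sub)
            sample.cube.patient_id = pid
            sample.cube.name = f"{pid}-img{i}"
            cohort.append(sample)
    return cohort
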