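"""Reflectance hypercube data model, file I/O, cropping and masking.

A hypercube is a 3-D reflectance array with two spatial axes and one spectral
axis: one reflectance spectrum per pixel.  Throughout the package the array is
indexed ``[row, col, band]`` with shape ``(Y, X, Z)`` (rows = Y, cols = X,
bands = Z), 0-based, and crop windows are half-open.  Reflectance is
dimensionless, nominally in [0, 1]; values may exceed 1 only where a simulated
specular saturation plateau was injected, and may dip below 0 in bands where
sensor noise was injected (no clipping after noise, so the stated variance is
preserved).

Two on-disk formats are supported:

* ENVI header + raw binary (``.hdr`` plus a sidecar raw file).  BSQ, BIL and
  BIP interleaves are read; BSQ (32-bit float, little endian) is written.
* A portable HDF5 container (``.h5``/``.hdf5``) holding the reflectance array
  (float32), the wavelength grid (float64) and optional metadata attributes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

#: Default foreground threshold on the per-pixel mean reflectance.
MASK_THRESHOLD_DEFAULT = 0.02

__all__ = [
    "MASK_THRESHOLD_DEFAULT",
    "WavelengthGrid",
    "Hypercube",
    "RGBImage",
    "BackgroundMask",
    "read_cube",
    "write_cube",
    "center_crop",
    "compute_background_mask",
    "render_band",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Band-center wavelengths in nm, strictly ascending, one per band."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def range(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def nearest_index(self, wavelength: float, *, require_in_range: bool = True) -> int:
        """Index of the band whose center is nearest ``wavelength``.

        Ties are broken toward the lower index.  By default the requested
        wavelength must lie within the grid range.
        """
        lo, hi = self.range
        if require_in_range and not (lo <= wavelength <= hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside grid range [{lo}, {hi}] nm"
            )
        return int(np.argmin(np.abs(self.values - wavelength)))

    def indices_in_range(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bands whose centers lie in [lo, hi] nm (inclusive)."""
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]

    @classmethod
    def linear(cls, lo: float = 400.0, hi: float = 1000.0, n: int = 384) -> "WavelengthGrid":
        """Evenly spaced grid; defaults mirror a ~400-1000 nm, 384-band sensor."""
        return cls(np.linspace(lo, hi, n))


@dataclass
class Hypercube:
    """Reflectance array ``(Y, X, Z)`` plus its wavelength grid and metadata."""

    data: np.ndarray
    wavelengths: WavelengthGrid
    patient_id: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"hypercube data must be 3-D (Y, X, Z), got ndim={data.ndim}")
        if data.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"band axis ({data.shape[2]}) does not match wavelength grid "
                f"({len(self.wavelengths)})"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("hypercube data contains NaN or Inf")
        self.data = data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, **meta) -> "Hypercube":
        """New cube sharing this cube's grid and metadata, with new data."""
        kw = dict(patient_id=self.patient_id, name=self.name)
        kw.update(meta)
        return Hypercube(data, self.wavelengths, **kw)


@dataclass
class RGBImage:
    """Three-channel image extracted at fixed wavelengths (order R, G, B)."""

    data: np.ndarray
    channel_wavelengths: tuple[float, float, float] = (650.0, 532.0, 473.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or data.shape[2] != 3:
            raise ValueError("RGB image must have shape (Y, X, 3)")
        if len(self.channel_wavelengths) != 3:
            raise ValueError("exactly three channel wavelengths required")
        self.data = data
        self.channel_wavelengths = tuple(float(w) for w in self.channel_wavelengths)


@dataclass
class BackgroundMask:
    """Boolean foreground map (True = tissue) over the cube's spatial grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2 or data.dtype != bool:
            raise ValueError("mask must be a 2-D boolean array")
        self.data = data

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# ENVI header + raw binary I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("float32"), 5: np.dtype("float64")}


def _envi_data_path(header_path: Path) -> Path:
    return header_path.with_suffix(".raw")


def _parse_envi_header(path: Path) -> dict[str, str]:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{path}: not an ENVI header (missing ENVI magic)")
    # Collapse brace-delimited multi-line values onto one line first.
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([a-zA-Z][a-zA-Z0-9 _]*?)\s*=\s*(\{.*?\}|[^\n]*)",
                         re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(text):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:].split("}")[0]
        fields[key] = val.strip()
    return fields


def _read_envi(path: Path) -> Hypercube:
    header = _parse_envi_header(path)
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in header:
            raise ValueError(f"{path}: ENVI header missing required field '{key}'")
    if "wavelength" not in header:
        raise ValueError(f"{path}: ENVI header lacks wavelength metadata")
    samples = int(header["samples"])  # X (cols)
    lines = int(header["lines"])      # Y (rows)
    bands = int(header["bands"])      # Z
    interleave = header["interleave"].lower()
    dtype_code = int(header["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"{path}: unsupported ENVI data type {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]
    if int(header.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    wavelengths = np.array(
        [float(w) for w in header["wavelength"].replace("\n", " ").split(",") if w.strip()]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"{path}: wavelength list length ({wavelengths.size}) does not match "
            f"band count ({bands})"
        )
    data_path = _envi_data_path(path)
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ValueError(f"{data_path}: file size does not match header dimensions")
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"{path}: unknown interleave '{interleave}'")
    data = np.ascontiguousarray(data.astype(dtype.newbyteorder("="), copy=False))
    return Hypercube(
        data,
        WavelengthGrid(wavelengths),
        patient_id=header.get("patient id") or None,
        name=header.get("cube name") or None,
    )


def _write_envi(cube: Hypercube, path: Path) -> None:
    rows, cols, bands = cube.shape
    data = np.ascontiguousarray(cube.data, dtype=np.float32)
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths.values)
    lines = [
        "ENVI",
        "description = {lumifuse reflectance hypercube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"wavelength = {{{wl}}}",
    ]
    if cube.patient_id:
        lines.append(f"patient id = {cube.patient_id}")
    if cube.name:
        lines.append(f"cube name = {cube.name}")
    path.write_text("\n".join(lines) + "\n")
    # BSQ: band-sequential layout on disk.
    data.transpose(2, 0, 1).tofile(_envi_data_path(path))


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

def _read_container(path: Path) -> Hypercube:
    with h5py.File(path, "r") as f:
        if "wavelengths" not in f:
            raise ValueError(f"{path}: container lacks wavelength metadata")
        data = f["reflectance"][()]
        wavelengths = f["wavelengths"][()]
        patient_id = f.attrs.get("patient_id")
        name = f.attrs.get("name")
    return Hypercube(
        data,
        WavelengthGrid(wavelengths),
        patient_id=str(patient_id) if patient_id is not None else None,
        name=str(name) if name is not None else None,
    )


def _write_container(cube: Hypercube, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=np.asarray(cube.data, dtype=np.float32))
        f.create_dataset("wavelengths", data=cube.wavelengths.values)
        if cube.patient_id is not None:
            f.attrs["patient_id"] = cube.patient_id
        if cube.name is not None:
            f.attrs["name"] = cube.name


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("envi", "container"):
            raise ValueError(f"unknown format '{format}'")
        return format
    suffix = path.suffix.lower()
    if suffix == ".hdr":
        return "envi"
    if suffix in (".h5", ".hdf5"):
        return "container"
    raise ValueError(
        f"cannot infer format from '{path}'; pass format='envi' or 'container'"
    )


def read_cube(path: str | Path, format: str | None = None) -> Hypercube:
    """Read a hypercube from an ENVI header or HDF5 container file.

    ENVI data is returned indexed ``[row, col, band]`` regardless of the
    on-disk interleave (BSQ/BIL/BIP all accepted).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_envi(path) if fmt == "envi" else _read_container(path)


def write_cube(cube: Hypercube, path: str | Path, format: str | None = None) -> None:
    """Write a hypercube; the file round-trips bit-exactly through read_cube.

    ENVI output is BSQ, 32-bit float, little endian (pass the ``.hdr`` path;
    the raw data lands in a ``.raw`` sidecar).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    if fmt == "envi":
        _write_envi(cube, path)
    else:
        _write_container(cube, path)


# ---------------------------------------------------------------------------
# Cropping, masking, rendering
# ---------------------------------------------------------------------------

def center_crop(cube: Hypercube, height: int, width: int) -> Hypercube:
    """Crop a centered ``height x width`` window.

    The window starts at ``ceil(Y/2) - ceil(height/2)``: when the leftover
    margin is odd, its extra pixel goes to the top/left margin.  This
    convention telescopes, so two successive center crops equal one crop to
    the smaller size.  Half-open windows; the wavelength grid is unchanged.
    """
    rows, cols, _ = cube.shape
    if height > rows or width > cols:
        raise ValueError(
            f"requested crop {height}x{width} exceeds input {rows}x{cols}"
        )
    if height < 1 or width < 1:
        raise ValueError("crop size must be at least 1x1")
    top = (rows + 1) // 2 - (height + 1) // 2
    left = (cols + 1) // 2 - (width + 1) // 2
    return cube.with_data(cube.data[top:top + height, left:left + width, :])


def compute_background_mask(
    cube: Hypercube, threshold: float = MASK_THRESHOLD_DEFAULT
) -> BackgroundMask:
    """Foreground = pixels whose mean reflectance across bands exceeds ``threshold``.

    The mean-over-bands rule is robust to single-band noise.  An all-background
    result raises a warning here; the metrics layer raises on an empty mask.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = cube.data.mean(axis=2) > threshold
    if not mask.any():
        warnings.warn(
            "background mask has no foreground pixels", RuntimeWarning, stacklevel=2
        )
    return BackgroundMask(mask)


def render_band(cube: Hypercube, wavelengths: float | Sequence[float]) -> np.ndarray:
    """Display helper: nearest-band grayscale or pseudocolor image.

    One wavelength yields a ``(Y, X)`` grayscale array; three yield a
    ``(Y, X, 3)`` pseudocolor array (e.g. 650/532/473 nm).  Values are clipped
    to [0, 1] for display only — the cube itself is untouched.
    """
    if np.isscalar(wavelengths):
        band = cube.wavelengths.nearest_index(float(wavelengths))  # type: ignore[arg-type]
        return np.clip(cube.data[:, :, band], 0.0, 1.0)
    wl = list(wavelengths)  # type: ignore[arg-type]
    if len(wl) != 3:
        raise ValueError("pass one wavelength (grayscale) or three (pseudocolor)")
    idx = [cube.wavelengths.nearest_index(float(w)) for w in wl]
    return np.clip(cube.data[:, :, idx], 0.0, 1.0)
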