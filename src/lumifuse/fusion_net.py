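"""Three-stage spatial-spectral reconstruction network and its losses.

The reconstruction maps a fused input — the LR-HSI bilinearly upsampled to
full resolution, with the bands nearest the RGB wavelengths overwritten by
the HR-RGB channels (band-replacement fusion) — to the high-resolution
hypercube.  Three 3x3 convolutions, stride 1, zero padding 1, with input and
output channel width both equal to the band count Z:

* stage A (fusion):    ``u = ReLU(conv_a(fused))``
* stage B (spatial):   ``prelim = u + conv_b(u)``        (residual)
* stage C (spectral):  ``final  = prelim + conv_c(prelim)``

The residual skips are a configuration flag (default on); with them, zeroed
B/C weights make the network the identity past stage A.  ReLU appears only
after the fusion stage so the reconstruction can reach values near zero.

Losses (each a plain mean over its difference stack):

* spatial  — MSE between first-order spatial difference maps (adjacent-pixel
  differences along rows and columns, per band) of the *preliminary* output
  and the reference; invariant to global constants.
* spectral — MSE between adjacent-band difference stacks of the *final*
  output and the reference; invariant to per-pixel constant offsets.
* fused    — plain MSE between the final output and the reference.

The total loss is their sum, back-propagated once per step.  Forward and
backward passes are written directly in NumPy (float64) via im2col; gradient
correctness is pinned by a finite-difference test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hypercube import Hypercube, RGBImage, WavelengthGrid
from .degrade import upsample

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "LossBreakdown",
    "init_weights",
    "fuse",
    "forward",
    "spatial_loss",
    "spectral_loss",
    "fused_loss",
    "total_loss",
    "loss_and_grads",
    "AdamState",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture constants: 3x3 kernels, stride 1, channel width = Z."""

    n_bands: int
    rgb_band_indices: tuple[int, int, int]
    residual_stages: bool = True

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("network needs at least two bands")
        if len(set(self.rgb_band_indices)) != 3:
            raise ValueError(
                f"RGB band indices collide: {self.rgb_band_indices} "
                "(two channels map to one band)"
            )
        for i in self.rgb_band_indices:
            if not (0 <= i < self.n_bands):
                raise ValueError(f"RGB band index {i} out of range")

    @classmethod
    def from_wavelengths(
        cls,
        grid: WavelengthGrid,
        rgb_wavelengths: tuple[float, float, float] = (650.0, 532.0, 473.0),
        residual_stages: bool = True,
    ) -> "NetworkConfig":
        idx = tuple(grid.nearest_index(float(w)) for w in rgb_wavelengths)
        return cls(len(grid), idx, residual_stages)  # type: ignore[arg-type]


@dataclass
class NetworkParams:
    """Weights of the three convolutions; each W has shape (3, 3, Z, Z)."""

    w_a: np.ndarray
    b_a: np.ndarray
    w_b: np.ndarray
    b_b: np.ndarray
    w_c: np.ndarray
    b_c: np.ndarray

    def arrays(self) -> list[np.ndarray]:
        return [self.w_a, self.b_a, self.w_b, self.b_b, self.w_c, self.b_c]

    def copy(self) -> "NetworkParams":
        return NetworkParams(*[a.copy() for a in self.arrays()])


def init_weights(config: NetworkConfig, seed: int = 0,
                 scheme: str = "near_identity") -> NetworkParams:
    """Initialize network weights.

    ``near_identity`` (default): stage A = delta-kernel channel identity plus
    small uniform noise; residual branches B and C start at zero, so the
    untrained network is ReLU(~identity) of its input — the standard
    zero-init-residual practice for restoration networks, which keeps short
    CPU training budgets workable.  ``kaiming``: small uniform fan-in-scaled
    init for all three layers.
    """
    z = config.n_bands
    rng = np.random.default_rng(seed)
    fan_in = 9 * z
    bound = float(np.sqrt(6.0 / fan_in))

    def uniform(scale: float) -> np.ndarray:
        return rng.uniform(-scale, scale, size=(3, 3, z, z))

    if scheme == "near_identity":
        w_a = uniform(0.05 * bound)
        w_a[1, 1] += np.eye(z)
        w_b = np.zeros((3, 3, z, z))
        w_c = np.zeros((3, 3, z, z))
    elif scheme == "kaiming":
        w_a, w_b, w_c = uniform(bound), uniform(bound), uniform(bound)
    else:
        raise ValueError(f"unknown init scheme '{scheme}'")
    zeros = np.zeros(z)
    return NetworkParams(w_a, zeros.copy(), w_b, zeros.copy(), w_c, zeros.copy())


# ---------------------------------------------------------------------------
# 3x3 convolution with zero padding 1 (shift-and-matmul formulation)
# ---------------------------------------------------------------------------

def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward conv; returns (output, cached zero-padded input)."""
    h, width, _ = x.shape
    xp = np.zeros((h + 2, width + 2, x.shape[2]), dtype=np.float64)
    xp[1:-1, 1:-1] = x
    out = np.broadcast_to(b, (h, width, w.shape[3])).copy()
    for ky in range(3):
        for kx in range(3):
            out += xp[ky:ky + h, kx:kx + width] @ w[ky, kx]
    return out, xp


def _conv3x3_backward(
    d_out: np.ndarray, xp: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dW, db, dX) of a conv given upstream dY and padded input."""
    h, width, _ = d_out.shape
    dw = np.empty_like(w)
    db = d_out.sum(axis=(0, 1))
    dxp = np.zeros_like(xp)
    for ky in range(3):
        for kx in range(3):
            patch = xp[ky:ky + h, kx:kx + width]
            dw[ky, kx] = np.tensordot(patch, d_out, axes=([0, 1], [0, 1]))
            dxp[ky:ky + h, kx:kx + width] += d_out @ w[ky, kx].T
    return dw, db, dxp[1:-1, 1:-1]


# ---------------------------------------------------------------------------
# Fusion and forward pass
# ---------------------------------------------------------------------------

def fuse(lr_hsi: Hypercube, hr_rgb: RGBImage, config: NetworkConfig) -> Hypercube:
    """Band-replacement fusion: upsample the LR-HSI, overwrite the RGB bands.

    The output has all Z bands at the HR-RGB's spatial resolution; bands at
    ``config.rgb_band_indices`` equal the HR-RGB channels bit-exactly and all
    other bands equal the bilinear upsample bit-exactly (the convolutions
    come later, so this holds regardless of weights).
    """
    lh, lw, lz = lr_hsi.shape
    hh, hw, _ = hr_rgb.data.shape
    if lz != config.n_bands:
        raise ValueError(f"LR-HSI has {lz} bands, config expects {config.n_bands}")
    if hh % lh or hw % lw:
        raise ValueError(
            f"LR spatial dims {lh}x{lw} do not divide HR dims {hh}x{hw}"
        )
    up = upsample(lr_hsi, (hh, hw))
    data = up.data
    for channel, band in enumerate(config.rgb_band_indices):
        data[:, :, band] = hr_rgb.data[:, :, channel]
    return up


def _forward_arrays(x: np.ndarray, params: NetworkParams, config: NetworkConfig):
    """Raw forward pass; returns (prelim, final, cache) in float64."""
    if x.shape[2] != config.n_bands:
        raise ValueError(f"input has {x.shape[2]} channels, expected {config.n_bands}")
    x = np.asarray(x, dtype=np.float64)
    a_pre, xp_a = _conv3x3(x, params.w_a, params.b_a)
    u = np.maximum(a_pre, 0.0)
    b_out, xp_b = _conv3x3(u, params.w_b, params.b_b)
    prelim = u + b_out if config.residual_stages else b_out
    c_out, xp_c = _conv3x3(prelim, params.w_c, params.b_c)
    final = prelim + c_out if config.residual_stages else c_out
    cache = dict(a_pre=a_pre, xp_a=xp_a, xp_b=xp_b, prelim=prelim, xp_c=xp_c)
    return prelim, final, cache


def forward(
    fused: Hypercube, params: NetworkParams, config: NetworkConfig
) -> tuple[Hypercube, Hypercube]:
    """Run the network; returns (preliminary HR cube, final HR cube)."""
    prelim, final, _ = _forward_arrays(fused.data, params, config)
    return fused.with_data(prelim), fused.with_data(final)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

@dataclass
class LossBreakdown:
    """Spatial + spectral + fused components and their sum."""

    spatial: float
    spectral: float
    fused: float

    @property
    def total(self) -> float:
        return self.spatial + self.spectral + self.fused


def _pair(estimate, reference) -> tuple[np.ndarray, np.ndarray]:
    e = estimate.data if isinstance(estimate, Hypercube) else np.asarray(estimate)
    r = reference.data if isinstance(reference, Hypercube) else np.asarray(reference)
    if e.shape != r.shape:
        raise ValueError(f"shape mismatch: {e.shape} vs {r.shape}")
    return e.astype(np.float64, copy=False), r.astype(np.float64, copy=False)


def spatial_loss(estimate, reference) -> float:
    """MSE between first-order spatial difference maps (rows and columns)."""
    e, r = _pair(estimate, reference)
    ex = (e[:, 1:, :] - e[:, :-1, :]) - (r[:, 1:, :] - r[:, :-1, :])
    ey = (e[1:, :, :] - e[:-1, :, :]) - (r[1:, :, :] - r[:-1, :, :])
    return float((np.sum(ex**2) + np.sum(ey**2)) / (ex.size + ey.size))


def spectral_loss(estimate, reference) -> float:
    """MSE between adjacent-band difference stacks."""
    e, r = _pair(estimate, reference)
    if e.shape[2] < 2:
        raise ValueError("spectral loss needs at least two bands")
    d = (e[:, :, 1:] - e[:, :, :-1]) - (r[:, :, 1:] - r[:, :, :-1])
    return float(np.mean(d**2))


def fused_loss(estimate, reference) -> float:
    """Plain mean squared error over all entries."""
    e, r = _pair(estimate, reference)
    return float(np.mean((e - r) ** 2))


def total_loss(preliminary_hr, final_hr, reference) -> LossBreakdown:
    """Spatial on the preliminary output; spectral and fused on the final."""
    return LossBreakdown(
        spatial=spatial_loss(preliminary_hr, reference),
        spectral=spectral_loss(final_hr, reference),
        fused=fused_loss(final_hr, reference),
    )


def _spatial_loss_grad(p: np.ndarray, r: np.ndarray) -> tuple[float, np.ndarray]:
    ex = (p[:, 1:, :] - p[:, :-1, :]) - (r[:, 1:, :] - r[:, :-1, :])
    ey = (p[1:, :, :] - p[:-1, :, :]) - (r[1:, :, :] - r[:-1, :, :])
    denom = ex.size + ey.size
    loss = (np.sum(ex**2) + np.sum(ey**2)) / denom
    grad = np.zeros_like(p)
    gx = 2.0 * ex / denom
    gy = 2.0 * ey / denom
    grad[:, 1:, :] += gx
    grad[:, :-1, :] -= gx
    grad[1:, :, :] += gy
    grad[:-1, :, :] -= gy
    return float(loss), grad


def _spectral_loss_grad(f: np.ndarray, r: np.ndarray) -> tuple[float, np.ndarray]:
    d = (f[:, :, 1:] - f[:, :, :-1]) - (r[:, :, 1:] - r[:, :, :-1])
    loss = np.mean(d**2)
    g = 2.0 * d / d.size
    grad = np.zeros_like(f)
    grad[:, :, 1:] += g
    grad[:, :, :-1] -= g
    return float(loss), grad


def loss_and_grads(
    fused_input: np.ndarray,
    reference: np.ndarray,
    params: NetworkParams,
    config: NetworkConfig,
) -> tuple[LossBreakdown, NetworkParams]:
    """One forward/backward pass; returns the loss breakdown and gradients.

    The gradients come back packed in a ``NetworkParams`` of the same shapes.
    """
    r = np.asarray(reference, dtype=np.float64)
    prelim, final, cache = _forward_arrays(fused_input, params, config)

    l_spat, d_prelim_direct = _spatial_loss_grad(prelim, r)
    l_spec, d_final_spec = _spectral_loss_grad(final, r)
    d_final_fus = 2.0 * (final - r) / final.size
    l_fus = float(np.mean((final - r) ** 2))

    d_final = d_final_spec + d_final_fus
    dw_c, db_c, d_prelim_c = _conv3x3_backward(d_final, cache["xp_c"], params.w_c)
    d_prelim = d_prelim_direct + d_prelim_c
    if config.residual_stages:
        d_prelim = d_prelim + d_final
    dw_b, db_b, d_u = _conv3x3_backward(d_prelim, cache["xp_b"], params.w_b)
    if config.residual_stages:
        d_u = d_u + d_prelim
    d_a_pre = d_u * (cache["a_pre"] > 0)
    dw_a, db_a, _ = _conv3x3_backward(d_a_pre, cache["xp_a"], params.w_a)
    grads = NetworkParams(dw_a, db_a, dw_b, db_b, dw_c, db_c)
    return LossBreakdown(l_spat, l_spec, l_fus), grads


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------

@dataclass
class AdamState:
    """Per-parameter Adam moments (beta1=0.9, beta2=0.999, eps=1e-8)."""

    m: list[np.ndarray] = field(default_factory=list)
    v: list[np.ndarray] = field(default_factory=list)
    t: int = 0

    def step(self, params: NetworkParams, grads: NetworkParams, lr: float) -> None:
        arrays = params.arrays()
        garrays = grads.arrays()
        if not self.m:
            self.m = [np.zeros_like(a) for a in arrays]
            self.v = [np.zeros_like(a) for a in arrays]
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for a, g, m, v in zip(arrays, garrays, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            a -= lr * mhat / (np.sqrt(vhat) + eps)
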