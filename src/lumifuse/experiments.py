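"""Experiment drivers: blur, noise, dead pixels, specular reflection.

One trained model (trained exclusively on the default blur-degraded LR-HSI /
clean HR-RGB pairs) serves all four experiments.  Each driver degrades the
held-out test references at the experiment's levels, reconstructs, and scores
against the reference with a shared background mask derived from the
reference.  The blur experiment also scores the bilinear-upsampling baseline
(upsampled LR-HSI, no network) — that column depends only on the degradation,
never on the weights.

Test-time blur *replaces* the LR-generation blur (a single Gaussian at the
stated kernel), rather than compounding it.  Corruptions (noise, dead pixels,
specular plateaus) are applied to the LR-HSI only; the HR-RGB stays clean.
Dead pixels and specular squares are placed uniformly within the 2-pixel-eroded
LR foreground so their high-resolution footprints are fully tissue; a dead or
saturated LR pixel maps to a ``down_factor x down_factor`` HR block for
localized scoring.

``run_phantom_study`` wires the whole pipeline end to end on a synthetic
cohort (generate, split, train, run all four experiments) and is what the
reproduction script drives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .degrade import (
    DegradationSpec,
    add_band_noise,
    extract_rgb,
    inject_dead_pixels,
    inject_specular,
    make_lr_hsi,
    upsample,
)
from .fusion_net import NetworkConfig, NetworkParams
from .hypercube import Hypercube, compute_background_mask
from .metrics import evaluate_pair, psnr as masked_psnr, rmse as masked_rmse, sam as masked_sam
from .phantom import PhantomSpec, derive_seed, generate_cohort
from .train import SplitAssignment, TrainConfig, TrainingLog, fit, reconstruct, split_cohort

__all__ = [
    "ExperimentTable",
    "DeadPixelReport",
    "SpecularReport",
    "StudyResult",
    "run_blur_experiment",
    "run_noise_experiment",
    "run_dead_pixel_experiment",
    "run_specular_experiment",
    "run_phantom_study",
]

_METRICS = ("PSNR", "RMSE", "ERGAS", "SAM")


@dataclass
class ExperimentTable:
    """Mean +/- sd of each metric per level, per method, over the test set."""

    experiment: str
    levels: list
    mean: pd.DataFrame      # rows: MultiIndex (method, metric); cols: levels
    sd: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def formatted(self) -> pd.DataFrame:
        """Cells rendered as 'mean ± sd' to 3 significant digits."""

        def fmt(m, s):
            return f"{float(m):.3g} ± {float(s):.3g}"

        return pd.DataFrame(
            np.vectorize(fmt)(self.mean.values, self.sd.values),
            index=self.mean.index,
            columns=self.mean.columns,
        )

    def to_csv(self, mean_path, sd_path=None) -> None:
        self.mean.to_csv(mean_path)
        if sd_path is not None:
            self.sd.to_csv(sd_path)


def _score(ref: Hypercube, est_data: np.ndarray, mask) -> dict[str, float]:
    report = evaluate_pair(ref, est_data, mask)
    return {"PSNR": report.psnr, "RMSE": report.rmse,
            "ERGAS": report.ergas, "SAM": report.sam}


def _build_table(experiment, levels, per_method_scores) -> ExperimentTable:
    methods = list(per_method_scores)
    index = pd.MultiIndex.from_product([methods, _METRICS],
                                       names=["method", "metric"])
    mean = pd.DataFrame(index=index, columns=levels, dtype=float)
    sd = pd.DataFrame(index=index, columns=levels, dtype=float)
    for method, by_level in per_method_scores.items():
        for level in levels:
            scores = by_level[level]       # list of dicts, one per test image
            for metric in _METRICS:
                vals = np.array([s[metric] for s in scores], dtype=float)
                mean.loc[(method, metric), level] = vals.mean()
                sd.loc[(method, metric), level] = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return ExperimentTable(experiment, list(levels), mean, sd)


def run_blur_experiment(
    test_samples,
    params: NetworkParams,
    net_config: NetworkConfig,
    base_spec: DegradationSpec,
    kernels=(5, 15, 25, 35),
) -> ExperimentTable:
    """Reconstruction vs bilinear-upsampling baseline across blur kernels."""
    scores = {"Reconstructed": {k: [] for k in kernels},
              "Upsampled": {k: [] for k in kernels}}
    for sample in test_samples:
        ref = getattr(sample, "cube", sample)
        mask = compute_background_mask(ref)
        rgb = extract_rgb(ref, base_spec.rgb_wavelengths)
        for kernel in kernels:
            spec = dataclasses.replace(base_spec, blur_kernel=int(kernel))
            lr = make_lr_hsi(ref, spec)
            recon = reconstruct(lr, rgb, params, net_config)
            baseline = upsample(lr, ref.shape[:2])
            scores["Reconstructed"][kernel].append(_score(ref, recon.data, mask))
            scores["Upsampled"][kernel].append(_score(ref, baseline.data, mask))
    return _build_table("blur", list(kernels), scores)


def run_noise_experiment(
    test_samples,
    params: NetworkParams,
    net_config: NetworkConfig,
    base_spec: DegradationSpec,
    variances=(0.01, 0.03, 0.05, 0.07),
    include_baseline: bool = False,
    seed: int = 0,
) -> ExperimentTable:
    """Reconstruction quality with uniform noise injected in the top bands.

    ``extras`` carries the band-restricted PSNR (bands inside the noise
    window only) of the reconstruction and of the noisy upsampled input, the
    direct check that the noise is suppressed rather than passed through.
    """
    methods = ["Reconstructed"] + (["Upsampled"] if include_baseline else [])
    scores = {m: {v: [] for v in variances} for m in methods}
    band_psnr_recon = {v: [] for v in variances}
    band_psnr_noisy = {v: [] for v in variances}
    for i, sample in enumerate(test_samples):
        ref = getattr(sample, "cube", sample)
        mask = compute_background_mask(ref)
        noise_bands = ref.wavelengths.indices_in_range(*base_spec.noise_band_range)
        rgb = extract_rgb(ref, base_spec.rgb_wavelengths)
        lr = make_lr_hsi(ref, base_spec)
        for v in variances:
            noisy = add_band_noise(lr, float(v), base_spec.noise_band_range,
                                   seed=derive_seed(seed, i, int(round(v * 1000))))
            recon = reconstruct(noisy, rgb, params, net_config)
            noisy_up = upsample(noisy, ref.shape[:2])
            scores["Reconstructed"][v].append(_score(ref, recon.data, mask))
            if include_baseline:
                scores["Upsampled"][v].append(_score(ref, noisy_up.data, mask))
            ref_sub = ref.data[:, :, noise_bands]
            _, p_recon = masked_psnr(ref_sub, recon.data[:, :, noise_bands], mask.data)
            _, p_noisy = masked_psnr(ref_sub, noisy_up.data[:, :, noise_bands], mask.data)
            band_psnr_recon[v].append(p_recon)
            band_psnr_noisy[v].append(p_noisy)
    table = _build_table("noise", list(variances), scores)
    table.extras = {
        "band_psnr_recon": {v: float(np.mean(vals)) for v, vals in band_psnr_recon.items()},
        "band_psnr_noisy_upsampled": {v: float(np.mean(vals))
                                      for v, vals in band_psnr_noisy.items()},
    }
    return table


def _eroded_foreground(cube: Hypercube) -> np.ndarray:
    mask = compute_background_mask(cube).data
    return ndimage.binary_erosion(mask, iterations=2)


def _hr_footprint(shape_hw, coords, factor: int) -> np.ndarray:
    """HR boolean mask covering the factor x factor block of each LR pixel."""
    fp = np.zeros(shape_hw, dtype=bool)
    for r, c in coords:
        fp[r * factor:(r + 1) * factor, c * factor:(c + 1) * factor] = True
    return fp


@dataclass
class DeadPixelReport:
    """Footprint-localized and whole-image scores for the dead-pixel run."""

    n_dead: int
    footprint_sam_recon: float
    footprint_sam_upsampled: float
    footprint_rmse_recon: float
    footprint_rmse_upsampled: float
    whole_image: ExperimentTable
    spectra: list[dict]     # per dead pixel: reference/recon/upsampled spectra


def run_dead_pixel_experiment(
    test_samples,
    params: NetworkParams,
    net_config: NetworkConfig,
    base_spec: DegradationSpec,
    n_dead: int = 12,
    seed: int = 0,
) -> DeadPixelReport:
    """Inject dead pixels into the LR-HSI, reconstruct, score their footprints."""
    factor = base_spec.down_factor
    scores = {"Reconstructed": {n_dead: []}, "Upsampled": {n_dead: []}}
    sam_recon, sam_up, rmse_recon, rmse_up = [], [], [], []
    spectra: list[dict] = []
    for i, sample in enumerate(test_samples):
        ref = getattr(sample, "cube", sample)
        mask = compute_background_mask(ref)
        rgb = extract_rgb(ref, base_spec.rgb_wavelengths)
        lr = make_lr_hsi(ref, base_spec)
        eroded = _eroded_foreground(lr)
        candidates = np.argwhere(eroded)
        if len(candidates) < n_dead:
            raise ValueError(
                f"only {len(candidates)} eroded-foreground LR pixels, need {n_dead}"
            )
        rng = np.random.default_rng(derive_seed(seed, i))
        chosen = candidates[rng.choice(len(candidates), size=n_dead, replace=False)]
        coords = [tuple(int(v) for v in rc) for rc in chosen]
        corrupted, _ = inject_dead_pixels(lr, coords=coords)
        recon = reconstruct(corrupted, rgb, params, net_config)
        baseline = upsample(corrupted, ref.shape[:2])
        scores["Reconstructed"][n_dead].append(_score(ref, recon.data, mask))
        scores["Upsampled"][n_dead].append(_score(ref, baseline.data, mask))
        if n_dead:
            fp = _hr_footprint(ref.shape[:2], coords, factor)
            s_r, _ = masked_sam(ref.data, recon.data, fp)
            s_u, _ = masked_sam(ref.data, baseline.data, fp)
            sam_recon.append(s_r)
            sam_up.append(s_u)
            rmse_recon.append(masked_rmse(ref.data, recon.data, fp))
            rmse_up.append(masked_rmse(ref.data, baseline.data, fp))
            for r, c in coords:
                hr_r = r * factor + factor // 2
                hr_c = c * factor + factor // 2
                spectra.append({
                    "sample": i, "lr_coord": (r, c),
                    "wavelengths": ref.wavelengths.values,
                    "reference": ref.data[hr_r, hr_c].copy(),
                    "reconstructed": recon.data[hr_r, hr_c].copy(),
                    "upsampled": baseline.data[hr_r, hr_c].copy(),
                })
    table = _build_table("dead", [n_dead], scores)
    agg = (lambda vals: float(np.mean(vals)) if vals else float("nan"))
    return DeadPixelReport(
        n_dead=n_dead,
        footprint_sam_recon=agg(sam_recon),
        footprint_sam_upsampled=agg(sam_up),
        footprint_rmse_recon=agg(rmse_recon),
        footprint_rmse_upsampled=agg(rmse_up),
        whole_image=table,
        spectra=spectra if n_dead else [],
    )


@dataclass
class SpecularReport:
    """Per-region scores for the specular-saturation run, ordered by size."""

    sizes: list[int]
    region_rmse: dict[int, float]       # spectral RMSE in the plateau window
    region_center_sam: dict[int, float]
    whole_image: ExperimentTable
    spectra: list[dict]


def _place_squares(eroded: np.ndarray, sizes, rng) -> list[tuple[int, int, int]]:
    """Disjoint size x size squares inside the eroded foreground.

    Squares are placed largest-first (small foregrounds leave few anchors for
    the big squares), drawing uniformly among the valid anchors: positions
    whose whole window is eroded foreground and free of earlier squares.
    The returned list follows the order of ``sizes``.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    for _ in range(50):                     # a draw can block a later square
        allowed = eroded.copy()
        placed: dict[int, tuple[int, int, int]] = {}
        for order, size in sorted(enumerate(sizes), key=lambda t: -t[1]):
            windows = sliding_window_view(allowed, (size, size))
            anchors = np.argwhere(windows.all(axis=(2, 3)))
            if len(anchors) == 0:
                placed = {}
                break
            r, c = anchors[int(rng.integers(len(anchors)))]
            allowed[r:r + size, c:c + size] = False
            placed[order] = (int(r), int(c), int(size))
        if placed:
            return [placed[i] for i in range(len(sizes))]
    raise ValueError(
        f"could not place disjoint squares of sizes {tuple(sizes)} "
        "inside the eroded foreground"
    )


def run_specular_experiment(
    test_samples,
    params: NetworkParams,
    net_config: NetworkConfig,
    base_spec: DegradationSpec,
    sizes=(2, 3, 4, 5),
    seed: int = 0,
) -> SpecularReport:
    """Inject saturation squares into the LR-HSI and score each footprint.

    Per-region spectral RMSE is computed over the HR footprint restricted to
    the plateau wavelength window; SAM is reported at each region's center
    pixel (full spectrum).
    """
    factor = base_spec.down_factor
    scores = {"Reconstructed": {s: [] for s in sizes}}
    region_rmse = {s: [] for s in sizes}
    region_sam = {s: [] for s in sizes}
    spectra: list[dict] = []
    for i, sample in enumerate(test_samples):
        ref = getattr(sample, "cube", sample)
        mask = compute_background_mask(ref)
        rgb = extract_rgb(ref, base_spec.rgb_wavelengths)
        lr = make_lr_hsi(ref, base_spec)
        eroded = _eroded_foreground(lr)
        rng = np.random.default_rng(derive_seed(seed, i))
        regions = _place_squares(eroded, sizes, rng)
        corrupted = inject_specular(lr, regions, base_spec.specular_band_range,
                                    base_spec.plateau_value)
        recon = reconstruct(corrupted, rgb, params, net_config)
        bands = ref.wavelengths.indices_in_range(*base_spec.specular_band_range)
        for (r, c, size) in regions:
            fp = _hr_footprint(ref.shape[:2], [(rr, cc)
                                               for rr in range(r, r + size)
                                               for cc in range(c, c + size)], factor)
            ref_sub = ref.data[:, :, bands]
            rec_sub = recon.data[:, :, bands]
            region_rmse[size].append(masked_rmse(ref_sub, rec_sub, fp))
            center_r = r * factor + (size * factor) // 2
            center_c = c * factor + (size * factor) // 2
            g = ref.data[center_r, center_c].astype(np.float64)
            e = recon.data[center_r, center_c].astype(np.float64)
            cosang = np.dot(g, e) / max(np.linalg.norm(g) * np.linalg.norm(e), 1e-300)
            region_sam[size].append(float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
            spectra.append({
                "sample": i, "size": size, "lr_region": (r, c, size),
                "wavelengths": ref.wavelengths.values,
                "reference": g, "reconstructed": e,
            })
        for size in sizes:
            scores["Reconstructed"][size].append(_score(ref, recon.data, mask))
    table = _build_table("specular", list(sizes), scores)
    return SpecularReport(
        sizes=list(sizes),
        region_rmse={s: float(np.mean(v)) for s, v in region_rmse.items()},
        region_center_sam={s: float(np.mean(v)) for s, v in region_sam.items()},
        whole_image=table,
        spectra=spectra,
    )


# ---------------------------------------------------------------------------
# End-to-end phantom study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Everything the end-to-end phantom study produces."""

    split: SplitAssignment
    log: TrainingLog
    params: NetworkParams
    net_config: NetworkConfig
    degradation: DegradationSpec
    blur: ExperimentTable
    noise: ExperimentTable
    dead: DeadPixelReport
    specular: SpecularReport
    n_train: int
    n_val: int
    n_test: int


def run_phantom_study(
    seed: int = 0,
    *,
    n_patients: int = 20,
    height: int = 64,
    width: int = 64,
    n_bands: int = 31,
    epochs: int = 1000,
    learning_rate: float = 1e-3,
    eval_interval: int = 10,
    n_dead: int = 12,
    blur_kernels=(5, 15, 25, 35),
    noise_variances=(0.01, 0.03, 0.05, 0.07),
    specular_sizes=(2, 3, 4, 5),
) -> StudyResult:
    """Generate a cohort, train once, run all four experiments.

    Defaults are the package's scaled-down study conditions: 20 single-image
    phantom patients at 64x64x31, split 12/4/4 by patient, one model trained
    on the default blur degradation and reused for every experiment.
    """
    spec = PhantomSpec(height, width, n_bands=n_bands, seed=derive_seed(seed, 1))
    cohort = generate_cohort(spec, n_patients, 1)
    split = split_cohort(cohort, seed=derive_seed(seed, 2))
    train_set = split.select(cohort, "train")
    val_set = split.select(cohort, "val")
    test_set = split.select(cohort, "test")

    degradation = DegradationSpec()
    net_config = NetworkConfig.from_wavelengths(
        cohort[0].cube.wavelengths, degradation.rgb_wavelengths
    )
    train_config = TrainConfig(
        max_epochs=epochs,
        learning_rate=learning_rate,
        eval_interval=eval_interval,
        seed=derive_seed(seed, 3),
        degradation=degradation,
    )
    params, log = fit(train_set, val_set, net_config, train_config)

    blur = run_blur_experiment(test_set, params, net_config, degradation,
                               kernels=blur_kernels)
    noise = run_noise_experiment(test_set, params, net_config, degradation,
                                 variances=noise_variances,
                                 seed=derive_seed(seed, 4))
    dead = run_dead_pixel_experiment(test_set, params, net_config, degradation,
                                     n_dead=n_dead, seed=derive_seed(seed, 5))
    specular = run_specular_experiment(test_set, params, net_config, degradation,
                                       sizes=specular_sizes,
                                       seed=derive_seed(seed, 6))
    return StudyResult(
        split=split, log=log, params=params, net_config=net_config,
        degradation=degradation, blur=blur, noise=noise, dead=dead,
        specular=specular,
        n_train=len(train_set), n_val=len(val_set), n_test=len(test_set),
    )
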