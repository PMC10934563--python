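"""Patient-grouped splitting, the optimization loop, and checkpoint selection.

The cohort is split 60/20/20 into train/validation/test with every image of a
patient confined to one split (no patient leakage).  Training iterates one
full image per optimization step (full-image steps; no patch batching),
minimizing the summed spatial + spectral + fused loss with Adam.  Every
``eval_interval`` epochs the model is scored on the validation set with
background-masked PSNR and SAM; the weights are checkpointed only when PSNR
strictly exceeds the best so far AND SAM is strictly below the best so far —
a dual-metric rule that is robust to either metric improving incidentally
(ties do not trigger a checkpoint).  "Early stopping" is best-checkpoint
selection over the full epoch budget: the run is not truncated unless an
optional patience is set, and the last checkpoint's weights are returned.

Everything is deterministic under fixed seeds (single-threaded NumPy).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .degrade import DegradationSpec, extract_rgb, make_lr_hsi
from .fusion_net import (
    AdamState,
    LossBreakdown,
    NetworkConfig,
    NetworkParams,
    _forward_arrays,
    fuse,
    init_weights,
    loss_and_grads,
)
from .hypercube import Hypercube, RGBImage, compute_background_mask
from .metrics import psnr as masked_psnr
from .metrics import sam as masked_sam
from .phantom import derive_seed

__all__ = [
    "SplitAssignment",
    "TrainConfig",
    "TrainingLog",
    "split_cohort",
    "fit",
    "reconstruct",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SplitAssignment:
    """Mapping patient_id -> split name; grouping invariant by construction."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def patients(self, split: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == split]

    def select(self, samples, split: str) -> list:
        ids = set(self.patients(split))
        return [s for s in samples if _patient_of(s) in ids]


def _patient_of(sample) -> str:
    cube = getattr(sample, "cube", sample)
    if cube.patient_id is None:
        raise ValueError("sample lacks a patient_id")
    return cube.patient_id


def _cube_of(sample) -> Hypercube:
    return getattr(sample, "cube", sample)


def split_cohort(
    samples,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Greedy patient-grouped 60/20/20 split.

    Patients are shuffled deterministically by ``seed`` and assigned, one at
    a time, to the split with the largest remaining image quota (ties broken
    train > val > test), so realized image counts track the target fractions
    as closely as the grouping allows.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    counts: dict[str, int] = {}
    for s in samples:
        pid = _patient_of(s)
        counts[pid] = counts.get(pid, 0) + 1
    patients = sorted(counts)
    if len(patients) < 3:
        raise ValueError(f"need at least 3 patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    n_images = sum(counts.values())
    names = ("train", "val", "test")
    deficit = {n: f * n_images for n, f in zip(names, fractions)}
    assignment: dict[str, str] = {}
    for pid in order:
        target = max(names, key=lambda n: deficit[n])
        assignment[pid] = target
        deficit[target] -= counts[pid]
    return SplitAssignment(assignment, tuple(fractions), seed)  # type: ignore[arg-type]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters plus the LR/RGB forward model."""

    max_epochs: int = 10_000
    learning_rate: float = 1e-4
    eval_interval: int = 10
    seed: int = 0
    degradation: DegradationSpec = field(default_factory=DegradationSpec)
    patience: int | None = None     # evals without a checkpoint before stopping
    lr_decay_every: int | None = None   # halve-style step decay, off by default
    lr_decay_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.eval_interval < 1:
            raise ValueError("eval_interval must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (0.0 < self.lr_decay_factor <= 1.0):
            raise ValueError("lr_decay_factor must be in (0, 1]")


@dataclass
class TrainingLog:
    """Per-epoch losses, validation evaluations, and checkpoint bookkeeping."""

    epoch_losses: list[dict[str, float]] = field(default_factory=list)
    evals: list[dict[str, float | int | bool]] = field(default_factory=list)
    checkpoint_epochs: list[int] = field(default_factory=list)
    train_patient_ids: list[str] = field(default_factory=list)
    val_patient_ids: list[str] = field(default_factory=list)


def _prepare(sample, degradation: DegradationSpec, config: NetworkConfig):
    """Precompute (fused input, reference, mask, lr, rgb) for one sample."""
    ref = _cube_of(sample)
    lr = make_lr_hsi(ref, degradation)
    rgb = extract_rgb(ref, degradation.rgb_wavelengths)
    fused = fuse(lr, rgb, config)
    mask = compute_background_mask(ref).data
    return {
        "fused": np.asarray(fused.data, dtype=np.float64),
        "ref": np.asarray(ref.data, dtype=np.float64),
        "mask": mask,
        "patient_id": ref.patient_id,
    }


def _validation_scores(prepared_val, params, config) -> tuple[float, float]:
    psnrs, sams = [], []
    for item in prepared_val:
        _, final, _ = _forward_arrays(item["fused"], params, config)
        _, p = masked_psnr(item["ref"], final, item["mask"])
        s, _ = masked_sam(item["ref"], final, item["mask"])
        psnrs.append(p)
        sams.append(s)
    return float(np.mean(psnrs)), float(np.mean(sams))


def fit(
    train_samples,
    val_samples,
    net_config: NetworkConfig,
    train_config: TrainConfig,
) -> tuple[NetworkParams, TrainingLog]:
    """Train the network; returns the last checkpointed weights and the log."""
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    prepared_train = [_prepare(s, train_config.degradation, net_config)
                      for s in train_samples]
    prepared_val = [_prepare(s, train_config.degradation, net_config)
                    for s in val_samples]

    log = TrainingLog(
        train_patient_ids=sorted({p["patient_id"] for p in prepared_train}),
        val_patient_ids=sorted({p["patient_id"] for p in prepared_val}),
    )
    leaked = set(log.train_patient_ids) & set(log.val_patient_ids)
    if leaked:
        raise ValueError(f"patient leakage between train and val: {sorted(leaked)}")

    params = init_weights(net_config, seed=derive_seed(train_config.seed, 0))
    adam = AdamState()
    best_psnr, best_sam = -np.inf, np.inf
    best_params: NetworkParams | None = None
    evals_since_checkpoint = 0

    lr = train_config.learning_rate
    for epoch in range(1, train_config.max_epochs + 1):
        if (train_config.lr_decay_every
                and epoch > 1 and (epoch - 1) % train_config.lr_decay_every == 0):
            lr *= train_config.lr_decay_factor
        order_rng = np.random.default_rng(derive_seed(train_config.seed, epoch))
        order = order_rng.permutation(len(prepared_train))
        losses: list[LossBreakdown] = []
        for idx in order:
            item = prepared_train[idx]
            breakdown, grads = loss_and_grads(
                item["fused"], item["ref"], params, net_config
            )
            if not np.isfinite(breakdown.total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss "
                    f"{breakdown.total}); lower the learning rate"
                )
            adam.step(params, grads, lr)
            losses.append(breakdown)
        log.epoch_losses.append({
            "epoch": epoch,
            "total": float(np.mean([b.total for b in losses])),
            "spatial": float(np.mean([b.spatial for b in losses])),
            "spectral": float(np.mean([b.spectral for b in losses])),
            "fused": float(np.mean([b.fused for b in losses])),
        })

        if epoch % train_config.eval_interval == 0:
            val_psnr, val_sam = _validation_scores(prepared_val, params, net_config)
            checkpointed = val_psnr > best_psnr and val_sam < best_sam
            if checkpointed:
                best_psnr, best_sam = val_psnr, val_sam
                best_params = params.copy()
                log.checkpoint_epochs.append(epoch)
                evals_since_checkpoint = 0
            else:
                evals_since_checkpoint += 1
            log.evals.append({
                "epoch": epoch,
                "psnr": val_psnr,
                "sam": val_sam,
                "checkpointed": checkpointed,
            })
            if (train_config.patience is not None
                    and evals_since_checkpoint >= train_config.patience):
                break

    if best_params is None:     # no eval ever ran (max_epochs < eval_interval)
        best_params = params.copy()
    return best_params, log


def reconstruct(
    lr_hsi: Hypercube,
    hr_rgb: RGBImage,
    params: NetworkParams,
    net_config: NetworkConfig,
) -> Hypercube:
    """Fuse the inputs and run the network; returns the final HR cube."""
    if lr_hsi.n_bands != net_config.n_bands:
        raise ValueError(
            f"LR-HSI has {lr_hsi.n_bands} bands, network expects {net_config.n_bands}"
        )
    fused = fuse(lr_hsi, hr_rgb, net_config)
    _, final, _ = _forward_arrays(fused.data, params, net_config)
    return lr_hsi.with_data(final)


# ---------------------------------------------------------------------------
# Checkpoint file: weights + config + seed, single file, versioned
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path, params: NetworkParams, config: NetworkConfig, seed: int) -> None:
    meta = {
        "version": _CHECKPOINT_VERSION,
        "n_bands": config.n_bands,
        "rgb_band_indices": list(config.rgb_band_indices),
        "residual_stages": config.residual_stages,
        "seed": seed,
    }
    np.savez(
        Path(path),
        meta=json.dumps(meta),
        w_a=params.w_a, b_a=params.b_a,
        w_b=params.w_b, b_b=params.b_b,
        w_c=params.w_c, b_c=params.b_c,
    )


def load_checkpoint(path) -> tuple[NetworkParams, NetworkConfig, int]:
    with np.load(Path(path), allow_pickle=False) as f:
        meta = json.loads(str(f["meta"]))
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        params = NetworkParams(
            f["w_a"], f["b_a"], f["w_b"], f["b_b"], f["w_c"], f["b_c"]
        )
    config = NetworkConfig(
        meta["n_bands"], tuple(meta["rgb_band_indices"]), meta["residual_stages"]
    )
    return params, config, int(meta["seed"])
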