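"""Training protocol and the design-space / ablation grids.

The reference protocol: 150 epochs, batch size 4, weight decay 5e-8, a
single x0.1 learning-rate drop after epoch 100, patient-level 60/20/20
train/validation/test split, and flip/rotate/scale augmentation.  Optimizer
choices are SGD, Adam and AdaBound.  The grid runners mirror the published
design-space tables: optimizer x channel plan, second-encoder kernel, skip
variant, and module ablation (plain U-Net / dual-encoder+attention /
full cascade).

All of it is runnable at desk scale on one CPU by shrinking images, widths,
sample counts and epochs through the same configuration objects; the
defaults of :func:`run_ablation` are chosen for that regime.  Every random
choice flows from integer-keyed generator streams, so a fixed seed
reproduces datasets, splits, augmentation and training histories bit for
bit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .losses import composite_loss
from .metrics import binarize, evaluate_slices
from .network import FSNet, FsNetConfig, PRESET_PLANS
from .phantom import ImagePair, PhantomSpec, generate_phantom

OPTIMIZERS = ("sgd", "adam", "adabound")
# conventional starting rates; only the decay step is part of the protocol
DEFAULT_LR = {"sgd": 1e-2, "adam": 1e-3, "adabound": 1e-3}


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 4
    weight_decay: float = 5e-8
    optimizer: str = "adabound"
    initial_lr: float | None = None
    lr_drop_epoch: int = 100
    lr_drop_factor: float = 0.1
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)
    split_level: str = "patient"
    augment: bool = True
    eta: float = 0.02
    gamma: float = 1.0

    def __post_init__(self):
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(f"optimizer must be one of {OPTIMIZERS}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.split_level not in ("patient", "slice"):
            raise ValueError("split_level must be 'patient' or 'slice'")

    @property
    def lr(self) -> float:
        return self.initial_lr if self.initial_lr is not None \
            else DEFAULT_LR[self.optimizer]


# --------------------------------------------------------------------------
# dataset handling
# --------------------------------------------------------------------------

def split_dataset(manifest: pd.DataFrame, fractions=(0.6, 0.2, 0.2),
                  seed: int = 0, level: str = "patient"):
    """Partition a manifest into train/validation/test.

    ``patient`` level permutes patient ids and assigns whole patients with
    largest-remainder rounding of the patient counts, so no patient's slices
    straddle two splits; ``slice`` level permutes rows directly.
    """
    if "patient_id" not in manifest.columns:
        raise ValueError("manifest needs a patient_id column")
    rng = np.random.default_rng(seed)
    if level == "patient":
        units = sorted(manifest["patient_id"].unique())
        if len(units) < 3:
            raise ValueError("need at least 3 patients to split")
    elif level == "slice":
        units = list(manifest.index)
    else:
        raise ValueError("level must be 'patient' or 'slice'")
    order = [units[i] for i in rng.permutation(len(units))]
    counts = _largest_remainder(len(units), fractions)
    bounds = np.cumsum([0] + counts)
    groups = [set(order[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]
    if level == "patient":
        return tuple(manifest[manifest["patient_id"].isin(g)].copy() for g in groups)
    return tuple(manifest.loc[sorted(g)].copy() for g in groups)


def _largest_remainder(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # most negative first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def augment(pair: ImagePair, rng) -> ImagePair:
    """Seeded geometric augmentation: each of {horizontal flip, rotation
    within +-15 degrees, scaling 0.9-1.1} is applied with probability 1/2,
    identically to CT, MRI and mask; the mask is re-binarized after
    interpolation and the output keeps the input size.

    All random draws happen up-front in a fixed order, so the generator
    stream consumption does not depend on which transforms fire.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    do = rng.random(3) < 0.5
    angle = rng.uniform(-15.0, 15.0)
    scale = rng.uniform(0.9, 1.1)

    ct, mri = pair.ct.copy(), pair.mri.copy()
    mask = pair.mask.astype(np.float64)
    if do[0]:
        ct, mri, mask = ct[:, ::-1], mri[:, ::-1], mask[:, ::-1]
    if do[1]:
        ct = ndimage.rotate(ct, angle, reshape=False, order=1, mode="constant")
        mri = ndimage.rotate(mri, angle, reshape=False, order=1, mode="constant")
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant")
    if do[2]:
        ct = _zoom_keep_size(ct, scale, order=1)
        mri = _zoom_keep_size(mri, scale, order=1)
        mask = _zoom_keep_size(mask, scale, order=0)
    return ImagePair(ct=np.ascontiguousarray(np.clip(ct, 0, 1)),
                     mri=np.ascontiguousarray(np.clip(mri, 0, 1)),
                     mask=np.ascontiguousarray(mask > 0.5).astype(np.uint8),
                     patient_id=pair.patient_id, slice_index=pair.slice_index)


def _zoom_keep_size(img: np.ndarray, scale: float, order: int) -> np.ndarray:
    """Scale about the image centre, keeping the array shape."""
    h, w = img.shape
    centre = np.array([(h - 1) / 2, (w - 1) / 2])
    matrix = np.eye(2) / scale
    offset = centre - matrix @ centre
    return ndimage.affine_transform(img, matrix, offset=offset, order=order,
                                    mode="constant", output_shape=img.shape)


def make_optimizer(config: TrainConfig, parameters):
    """Named optimizer with weight decay and the single-step lr schedule."""
    lr = config.lr
    if config.optimizer == "sgd":
        opt = nn.SGD(parameters, lr=lr, weight_decay=config.weight_decay)
    elif config.optimizer == "adam":
        opt = nn.Adam(parameters, lr=lr, weight_decay=config.weight_decay)
    else:
        opt = nn.AdaBound(parameters, lr=lr, weight_decay=config.weight_decay)
    sched = nn.StepLR(opt, drop_epoch=config.lr_drop_epoch,
                      factor=config.lr_drop_factor)
    return opt, sched


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path: str, model: FSNet, extra: dict | None = None) -> None:
    state = model.state_dict()
    meta = {"config": model.config.to_dict(), **(extra or {})}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str) -> tuple[FSNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = FSNet(FsNetConfig.from_dict(meta.pop("config")))
    model.load_state_dict(state)
    return model, meta


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

def _batch_arrays(pairs: list[ImagePair], dtype):
    ct = np.stack([p.ct for p in pairs])[:, None].astype(dtype)
    mri = np.stack([p.mri for p in pairs])[:, None].astype(dtype)
    mask = np.stack([p.mask for p in pairs])[:, None].astype(dtype)
    return nn.Tensor(ct), nn.Tensor(mri), mask


def predict(model: FSNet, pairs: list[ImagePair], batch_size: int = 4) -> np.ndarray:
    """Probability maps (n, H, W) in eval mode."""
    model.eval()
    outs = []
    for i in range(0, len(pairs), batch_size):
        ct, mri, _ = _batch_arrays(pairs[i:i + batch_size], model.config.dtype)
        prob, _, _ = model(ct, mri, mode="inference")
        outs.append(prob.data[:, 0])
    return np.concatenate(outs, axis=0)


def validation_dice(model: FSNet, pairs: list[ImagePair], batch_size: int = 4,
                    threshold: float = 0.5) -> float:
    probs = predict(model, pairs, batch_size)
    _, summary = evaluate_slices((binarize(p, threshold) for p in probs),
                                 (p.mask for p in pairs))
    return summary.dc


def train(model: FSNet, train_pairs: list[ImagePair],
          val_pairs: list[ImagePair] | None, config: TrainConfig,
          out_dir: str | None = None, start_epoch: int = 1,
          optimizer=None, scheduler=None):
    """Seeded epoch loop; returns (history DataFrame, best state dict).

    Per epoch: shuffle, augment (if enabled), forward the cascade in train
    mode, build the composite loss, backprop, step.  Validation Dice is
    computed each epoch and the best-validation weights are kept.  Epoch
    RNG streams are keyed (seed, epoch), so a run resumed from epoch k with
    the same seed consumes identical randomness from epoch k on.
    """
    if optimizer is None:
        optimizer, scheduler = make_optimizer(config, model.parameters())
    history = []
    best = {"dc": -1.0, "state": None, "epoch": 0}
    use_fusion = model.config.use_fusion_subnet
    for epoch in range(start_epoch, config.epochs + 1):
        lr = scheduler.set_epoch(epoch)
        rng = np.random.default_rng([config.seed, epoch])
        order = rng.permutation(len(train_pairs))
        model.train()
        sums = {"mse": 0.0, "ssim_loss": 0.0, "bce": 0.0, "total": 0.0}
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            batch = [train_pairs[j] for j in order[i:i + config.batch_size]]
            if config.augment:
                batch = [augment(p, rng) for p in batch]
            ct, mri, mask = _batch_arrays(batch, model.config.dtype)
            prob, fused, recon = model(ct, mri, mode="train")
            stacked = nn.concat([ct, mri], axis=1)
            comps = composite_loss(
                recon if use_fusion else None, stacked,
                fused if use_fusion else None, prob, mask,
                eta=config.eta, gamma=config.gamma)
            vals = comps.as_floats()
            if not np.isfinite(vals["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {vals}")
            model.zero_grad()
            comps.total.backward()
            optimizer.step()
            for k in sums:
                sums[k] += vals[k]
            n_batches += 1
        row = {"epoch": epoch, "lr": lr,
               **{("train_loss" if k == "total" else k): v / max(n_batches, 1)
                  for k, v in sums.items()}}
        if val_pairs:
            row["val_dc"] = validation_dice(model, val_pairs, config.batch_size)
            if row["val_dc"] > best["dc"]:
                best = {"dc": row["val_dc"], "state": model.state_dict(),
                        "epoch": epoch}
        history.append(row)
    hist = pd.DataFrame(history)
    if best["state"] is None:
        best = {"dc": float("nan"), "state": model.state_dict(),
                "epoch": config.epochs}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        hist.to_csv(os.path.join(out_dir, "history.csv"), index=False)
        save_checkpoint(os.path.join(out_dir, "best.npz"), model,
                        {"best_epoch": best["epoch"], "best_val_dc": best["dc"]})
    return hist, best


# --------------------------------------------------------------------------
# ablation grids
# --------------------------------------------------------------------------

@dataclass
class AblationSettings:
    """Desk-scale defaults for the grid runs; every field is adjustable."""

    image_size: int = 32
    n_samples: int = 24
    slices_per_patient: int = 4
    epochs: int = 6
    batch_size: int = 4
    # grid cells that do not vary the plan use this narrow one
    base_widths: tuple[int, ...] = (8, 16, 32, 64, 128)
    # the optimizer-x-plan grid divides the presets by this, keeping the
    # wide/narrow relation between "(32)" and "(16)"
    plan_scale: int = 2
    fusion_widths: tuple[int, ...] = (8, 16, 32)
    seed: int = 0


def _scaled_plan(name: str, scale: int) -> tuple[int, ...]:
    widths = tuple(w // scale for w in PRESET_PLANS[name])
    if widths[0] < 8:
        raise ValueError(f"plan {name} scaled by {scale} drops below width 8")
    return widths


GRID_NAMES = ("table1", "table2", "table3", "table4")


def _grid_cells(grid: str, settings: AblationSettings):
    """Yield (label, FsNetConfig overrides, TrainConfig overrides)."""
    if grid == "table1":
        for opt, plan in [("adam", "(32)"), ("adabound", "(32)"),
                          ("sgd", "(32)"), ("adabound", "(16)")]:
            yield (f"{opt}+{plan}",
                   {"channel_plan": _scaled_plan(plan, settings.plan_scale)},
                   {"optimizer": opt})
    elif grid == "table2":
        for kern in ("3x3", "5x5", "2x2-0101", "2x2-1010"):
            yield (f"3x3-{kern}", {"encoder_b_kernel": kern}, {})
    elif grid == "table3":
        for variant in ("a", "b", "c", "d"):
            yield (variant, {"skip_variant": variant}, {})
    elif grid == "table4":
        yield ("U-Net", {"use_csab": False, "use_dual_encoder": False,
                         "use_fusion_subnet": False}, {})
        yield ("DECSAU-Net", {"use_fusion_subnet": False}, {})
        yield ("F-S-Net", {}, {})
    else:
        raise ValueError(f"unknown grid {grid!r}; choose from {GRID_NAMES}")


def run_ablation(grid: str, settings: AblationSettings | None = None,
                 out_path: str | None = None) -> pd.DataFrame:
    """Train every cell of one design grid on identical seeded phantoms and
    report ACC/PPV/JS/DC on the held-out test patients."""
    settings = settings or AblationSettings()
    spec = PhantomSpec(image_size=settings.image_size,
                       n_samples=settings.n_samples,
                       slices_per_patient=settings.slices_per_patient,
                       seed=settings.seed)
    pairs = [generate_phantom(spec, i) for i in range(spec.n_samples)]
    manifest = pd.DataFrame({"patient_id": [p.patient_id for p in pairs],
                             "slice_index": [p.slice_index for p in pairs],
                             "row": range(len(pairs))})
    tr_m, va_m, te_m = split_dataset(manifest, seed=settings.seed)
    groups = [[pairs[i] for i in m["row"]] for m in (tr_m, va_m, te_m)]
    rows = []
    for label, net_over, train_over in _grid_cells(grid, settings):
        net_cfg = FsNetConfig(
            channel_plan=net_over.pop("channel_plan", settings.base_widths),
            input_size=settings.image_size,
            fusion_widths=settings.fusion_widths, **net_over)
        tr_cfg = TrainConfig(epochs=settings.epochs,
                             batch_size=settings.batch_size,
                             seed=settings.seed,
                             lr_drop_epoch=max(settings.epochs - 1, 1),
                             **train_over)
        nn.manual_seed(settings.seed)
        model = FSNet(net_cfg)
        train(model, groups[0], groups[1], tr_cfg)
        probs = predict(model, groups[2], settings.batch_size)
        _, summary = evaluate_slices((binarize(p) for p in probs),
                                     (p.mask for p in groups[2]))
        rows.append({"cell": label, "acc": summary.acc, "ppv": summary.ppv,
                     "js": summary.js, "dc": summary.dc})
    table = pd.DataFrame(rows)
    if out_path:
        table.to_csv(out_path, index=False)
    return table
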