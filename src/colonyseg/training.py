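"""Model training: subset assignment, augmentation, losses, scheduling.

Defaults follow the tool's standard configuration: distance method, Ranger
optimizer, five models trained per run, batch size four.  New crops are
assigned to the train/validation/test subsets by a deterministic
largest-deficit rule with target fractions 0.600 / 0.225 / 0.175, which for
13 sequential crops yields an 8/3/2 split and for 22 crops a 13/5/4 split.

Training applies flip, rotation, scaling, contrast, blur and noise
augmentations; the boundary method is trained with a weighted sum of cross
entropy and channel-wise Dice loss, the distance method with a smooth L1
loss.  The epoch budget adapts to the training-set size and crop size, the
learning rate is reduced on validation-loss plateaus, and early stopping
triggers once the validation loss stops improving.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import labelrep, nn
from .network import ModelSpec, build_model, percentile_normalize

__all__ = [
    "TrainConfig",
    "Crop",
    "TrainingSet",
    "SUBSET_FRACTIONS",
    "ALLOWED_CROP_SIZES",
    "assign_subset",
    "augment",
    "boundary_loss",
    "distance_loss",
    "max_epochs",
    "train_models",
]

SUBSET_FRACTIONS = {"train": 0.600, "val": 0.225, "test": 0.175}
_SUBSET_ORDER = ("train", "val", "test")  # tie-break priority
ALLOWED_CROP_SIZES = (128, 256, 320, 512, 768, 1024)


@dataclass
class TrainConfig:
    method: str = "distance"
    optimizer: str = "ranger"
    batch_size: int = 4
    n_models: int = 5
    seed: int = 0
    crop_size: int = 128
    lr_start: float | None = None  # default depends on the optimizer
    lr_min: float = 6e-5
    plateau_factor: float = 0.25
    plateau_patience: int | None = None  # default: max(5, epochs_max // 12)
    stop_patience: int | None = None  # default: max(10, epochs_max // 8)
    epsilon_improve: float = 1e-4
    epochs_max: int | None = None  # default: auto from data and crop size
    param_budget: int | None = None  # None -> full-size network
    ce_weight: float = 1.0
    dice_weight: float = 1.0

    def resolved_lr(self) -> float:
        if self.lr_start is not None:
            return self.lr_start
        return 8e-4 if self.optimizer == "adam" else 6e-3


@dataclass
class Crop:
    image: np.ndarray
    mask: np.ndarray
    subset: str = "train"
    name: str = ""


@dataclass
class TrainingSet:
    crops: list[Crop]
    crop_size: int

    def __post_init__(self) -> None:
        if self.crop_size not in ALLOWED_CROP_SIZES:
            raise ValueError(f"crop_size must be one of {ALLOWED_CROP_SIZES}")
        for c in self.crops:
            if c.image.shape != (self.crop_size, self.crop_size) or c.mask.shape != c.image.shape:
                raise ValueError("crop image/mask shapes must equal crop_size x crop_size")

    def subset(self, name: str) -> list[Crop]:
        return [c for c in self.crops if c.subset == name]


def assign_subset(existing_counts: dict[str, int], explicit: str | None = None) -> str:
    """Deterministic greedy largest-deficit assignment of the next crop.

    Picks the subset maximizing ``target_fraction * (n + 1) - count`` where
    ``n`` is the total already assigned; ties break train > val > test.
    ``explicit`` overrides the automatic choice.
    """
    if explicit is not None:
        if explicit not in _SUBSET_ORDER:
            raise ValueError(f"unknown subset {explicit!r}")
        return explicit
    n = sum(existing_counts.get(s, 0) for s in _SUBSET_ORDER)
    if any(v < 0 for v in existing_counts.values()):
        raise ValueError("counts must be non-negative")
    deficits = {
        s: SUBSET_FRACTIONS[s] * (n + 1) - existing_counts.get(s, 0)
        for s in _SUBSET_ORDER
    }
    return max(_SUBSET_ORDER, key=lambda s: (deficits[s], -_SUBSET_ORDER.index(s)))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _rescale_pair(image: np.ndarray, mask: np.ndarray, factor: float):
    """Zoom image (linear) and mask (nearest), then crop/pad back to size."""
    h, w = image.shape
    zi = ndi.zoom(image, factor, order=1)
    zm = ndi.zoom(mask.astype(np.int32), factor, order=0)
    out_i = np.zeros_like(image)
    out_m = np.zeros_like(mask)
    zh, zw = zi.shape
    if zh >= h:
        y0 = (zh - h) // 2
        x0 = (zw - w) // 2
        return zi[y0 : y0 + h, x0 : x0 + w], zm[y0 : y0 + h, x0 : x0 + w].astype(mask.dtype)
    y0 = (h - zh) // 2
    x0 = (w - zw) // 2
    out_i[...] = np.median(zi)
    out_i[y0 : y0 + zh, x0 : x0 + zw] = zi
    out_m[y0 : y0 + zh, x0 : x0 + zw] = zm.astype(mask.dtype)
    return out_i, out_m


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    method: str,
    seed: int,
    cutoff_radius: float | None = None,
):
    """One stochastic augmentation draw; returns (image, target).

    Geometric transforms (flips, 90-degree rotations, scaling) are applied
    identically to image and mask, and the training target is recomputed
    from the transformed mask, so distance targets stay geometrically
    consistent.  Photometric transforms (contrast, blur, noise) touch only
    the image.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image, np.float32)
    msk = np.asarray(mask)
    if rng.random() < 0.5:
        img, msk = img[::-1].copy(), msk[::-1].copy()
    if rng.random() < 0.5:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    k = int(rng.integers(0, 4))
    if k:
        img, msk = np.rot90(img, k).copy(), np.rot90(msk, k).copy()
    factor = rng.uniform(0.85, 1.15)
    img, msk = _rescale_pair(img, msk, factor)
    # photometric (image only)
    img = img * rng.uniform(0.7, 1.3)
    sigma = rng.uniform(0.0, 1.5)
    if sigma > 0.05:
        img = ndi.gaussian_filter(img, sigma)
    rng_range = float(img.max() - img.min()) or 1.0
    img = img + rng.uniform(0.0, 0.05) * rng_range * rng.standard_normal(img.shape)
    target = labelrep.make_targets(msk, method, cutoff_radius=cutoff_radius)
    return img.astype(np.float32), target


# ---------------------------------------------------------------------------
# losses (on predicted probabilities / maps; gradients live in the trainer)
# ---------------------------------------------------------------------------

_DICE_SMOOTH = 1.0
_SMOOTH_L1_BETA = 1.0


def boundary_loss(
    pred_probs: np.ndarray,
    target_onehot: np.ndarray,
    ce_weight: float = 1.0,
    dice_weight: float = 1.0,
) -> float:
    """Weighted sum of pixel-mean cross entropy and channel-wise Dice loss."""
    if pred_probs.shape != target_onehot.shape:
        raise ValueError("shape mismatch")
    p = np.clip(np.asarray(pred_probs, np.float64), 1e-12, 1.0)
    t = np.asarray(target_onehot, np.float64)
    caxis = 0 if p.ndim == 3 else 1
    ce = float(-(t * np.log(p)).sum(axis=caxis).mean())
    spatial = tuple(i for i in range(p.ndim) if i != caxis)
    inter = (p * t).sum(axis=spatial)
    denom = p.sum(axis=spatial) + t.sum(axis=spatial)
    dice = (2.0 * inter + _DICE_SMOOTH) / (denom + _DICE_SMOOTH)
    return ce_weight * ce + dice_weight * float((1.0 - dice).mean())


def _smooth_l1(x: np.ndarray, beta: float = _SMOOTH_L1_BETA) -> np.ndarray:
    ax = np.abs(x)
    return np.where(ax < beta, 0.5 * x * x / beta, ax - 0.5 * beta)


def distance_loss(pred, target) -> float:
    """Smooth L1 (beta = 1), pixel-mean per map, summed over the two maps."""
    pc, pn = pred
    tc, tn = target
    if pc.shape != tc.shape or pn.shape != tn.shape:
        raise ValueError("shape mismatch")
    return float(_smooth_l1(np.asarray(pc) - tc).mean() + _smooth_l1(np.asarray(pn) - tn).mean())


def max_epochs(n_train_crops: int, crop_size: int) -> int:
    """Automatic epoch budget: more crops or larger crops mean fewer epochs."""
    if n_train_crops < 1:
        raise ValueError("need at least one training crop")
    e = int(np.clip(round(1120 / n_train_crops), 40, 200))
    return max(20, int(round(e * 128 / crop_size)))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _boundary_loss_and_grad(logits, target, ce_w, dice_w):
    """Loss and gradient w.r.t. logits for CE + channel-wise Dice."""
    p = _softmax(logits)
    n, c, h, w = p.shape
    m = n * h * w
    t = target
    ce = float(-(t * np.log(np.clip(p, 1e-12, 1.0))).sum() / m)
    dce = (p - t) / m
    spatial = (0, 2, 3)
    inter = (p * t).sum(axis=spatial)
    psum = p.sum(axis=spatial)
    tsum = t.sum(axis=spatial)
    denom = psum + tsum + _DICE_SMOOTH
    dice = (2.0 * inter + _DICE_SMOOTH) / denom
    # d(1 - dice_c)/dp = -(2 t denom - (2 inter + smooth)) / denom^2, mean over c
    ddice_dp = -(2.0 * t * denom[None, :, None, None] - (2.0 * inter + _DICE_SMOOTH)[None, :, None, None]) / (
        denom[None, :, None, None] ** 2
    ) / c
    dLdp = dice_w * ddice_dp
    # chain through softmax for the dice part; CE part is already in logits
    dot = (dLdp * p).sum(axis=1, keepdims=True)
    dlogits = ce_w * dce + p * (dLdp - dot)
    loss = ce_w * ce + dice_w * float((1.0 - dice).mean())
    return loss, dlogits.astype(np.float32)


def _distance_loss_and_grad(outs, targets):
    """Smooth-L1 loss and per-decoder gradients."""
    loss = 0.0
    grads = []
    for out, tgt in zip(outs, targets):
        x = out - tgt
        ax = np.abs(x)
        loss += float(_smooth_l1(x).mean())
        g = np.where(ax < _SMOOTH_L1_BETA, x / _SMOOTH_L1_BETA, np.sign(x)) / x[0].size / 1.0
        g /= x.shape[0]
        grads.append(g.astype(np.float32))
    return loss, grads


def _make_optimizer(cfg: TrainConfig, params):
    lr = cfg.resolved_lr()
    if cfg.optimizer == "adam":
        return nn.Adam(params, lr=lr)
    if cfg.optimizer == "ranger":
        return nn.ranger(params, lr=lr)
    raise ValueError(f"unknown optimizer {cfg.optimizer!r}")


def _epoch_loss(net, images, targets, method, cfg, batch_size):
    """Validation loss: same loss as training, no augmentation."""
    total = 0.0
    n = len(images)
    for i in range(0, n, batch_size):
        xb = np.stack(images[i : i + batch_size])
        outs = net.forward(xb, train=False)
        if method == "boundary":
            tb = np.stack(targets[i : i + batch_size])
            loss, _ = _boundary_loss_and_grad(outs[0], tb, cfg.ce_weight, cfg.dice_weight)
        else:
            tb = np.stack(targets[i : i + batch_size])
            loss, _ = _distance_loss_and_grad(
                [outs[0][:, 0], outs[1][:, 0]], [tb[:, 0], tb[:, 1]]
            )
        total += loss * len(xb)
    return total / n


def train_models(
    tset: TrainingSet,
    cfg: TrainConfig | None = None,
    out_dir: str | None = None,
) -> list[ModelSpec]:
    """Train ``cfg.n_models`` models with seeds seed, seed+1, ...

    Per model: optimizer per config, reduce-on-plateau learning-rate
    schedule, early stopping on stalled validation loss, best-validation
    weights kept.  Writes one training-log CSV per model when ``out_dir`` is
    given.  Returns one ModelSpec per model.
    """
    cfg = cfg or TrainConfig()
    train_crops = tset.subset("train")
    val_crops = tset.subset("val")
    if not train_crops or not val_crops:
        raise ValueError("training set needs at least one train and one val crop")

    epochs_max = cfg.epochs_max or max_epochs(len(train_crops), tset.crop_size)
    plateau_patience = cfg.plateau_patience or max(5, epochs_max // 12)
    stop_patience = cfg.stop_patience or max(10, epochs_max // 8)

    cutoff = None
    if cfg.method == "distance":
        cutoff = labelrep.default_cutoff_radius([c.mask for c in tset.crops])

    val_images = [percentile_normalize(c.image) for c in val_crops]
    val_targets = [
        labelrep.make_targets(c.mask, cfg.method, cutoff_radius=cutoff) for c in val_crops
    ]

    specs: list[ModelSpec] = []
    for m in range(cfg.n_models):
        model_seed = cfg.seed + m
        spec = train_one(
            tset,
            cfg,
            model_seed,
            epochs_max,
            plateau_patience,
            stop_patience,
            cutoff,
            (val_images, val_targets),
            out_dir=out_dir,
            model_id=f"{cfg.method}_{cfg.optimizer}_{model_seed:03d}",
        )
        specs.append(spec)
    return specs


def train_one(
    tset: TrainingSet,
    cfg: TrainConfig,
    model_seed: int,
    epochs_max: int,
    plateau_patience: int,
    stop_patience: int,
    cutoff: float | None,
    val_data,
    out_dir: str | None = None,
    model_id: str = "",
) -> ModelSpec:
    """Train a single model (see :func:`train_models`)."""
    rng = np.random.default_rng(model_seed)
    spec = build_model(
        cfg.method, budget=cfg.param_budget, seed=model_seed, model_id=model_id
    )
    net = spec.net
    opt = _make_optimizer(cfg, net.params)
    train_crops = tset.subset("train")
    val_images, val_targets = val_data

    best_val = np.inf
    best_state = None
    best_epoch = 0
    since_improve = 0
    since_plateau = 0
    log_rows = []
    final_train = np.nan
    epochs_run = 0

    for epoch in range(1, epochs_max + 1):
        order = rng.permutation(len(train_crops))
        epoch_loss = 0.0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            imgs, tgts = [], []
            for j in idx:
                c = train_crops[j]
                aug_seed = int(rng.integers(0, 2**31 - 1))
                img, tgt = augment(c.image, c.mask, cfg.method, aug_seed, cutoff)
                imgs.append(percentile_normalize(img))
                tgts.append(tgt)
            xb = np.stack(imgs)
            tb = np.stack(tgts)
            net.zero_grad()
            outs = net.forward(xb, train=True)
            if cfg.method == "boundary":
                loss, dlogits = _boundary_loss_and_grad(
                    outs[0], tb, cfg.ce_weight, cfg.dice_weight
                )
                net.backward([dlogits])
            else:
                loss, grads = _distance_loss_and_grad(
                    [outs[0][:, 0], outs[1][:, 0]], [tb[:, 0], tb[:, 1]]
                )
                net.backward([grads[0][:, None], grads[1][:, None]])
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= len(order)
        final_train = epoch_loss
        net.finalize_bn()  # precise eval-mode statistics for this epoch
        val_loss = _epoch_loss(net, val_images, val_targets, cfg.method, cfg, cfg.batch_size)
        log_rows.append((epoch, opt.lr, epoch_loss, val_loss))
        epochs_run = epoch

        if val_loss < best_val - cfg.epsilon_improve:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            since_improve = 0
            since_plateau = 0
        else:
            since_improve += 1
            since_plateau += 1
        if since_plateau >= plateau_patience and opt.lr > cfg.lr_min:
            opt.lr = max(cfg.lr_min, opt.lr * cfg.plateau_factor)
            since_plateau = 0
        if since_improve >= stop_patience:
            break

    if best_state is not None:
        net.set_state(best_state)
    spec.train_meta = {
        "optimizer": cfg.optimizer,
        "seed": model_seed,
        "epochs_run": epochs_run,
        "epochs_max": epochs_max,
        "best_epoch": best_epoch,
        "best_val_loss": float(best_val),
        "final_train_loss": float(final_train),
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, f"{spec.model_id}_log.csv"), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "lr", "train_loss", "val_loss"])
            for row in log_rows:
                writer.writerow([row[0], f"{row[1]:.2e}", f"{row[2]:.6f}", f"{row[3]:.6f}"])
    return spec
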