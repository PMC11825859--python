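"""Losses, augmentation, regularization and the staged training algorithm.

Training proceeds in stages: the detail (level-2) and context (level-3)
single models are pre-trained with their encoder frozen for the first part
of the run; their encoders (and the detail decoder) are then transferred
into the dual model, which first trains only the cross-attention fusion
with everything else frozen, and is finally unfrozen end to end.  After
validation-based model selection, the selected schedule is re-run on the
union of training and validation data up to the best epoch.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import nn
from .models import (ModelConfig, SingleSegModel, DualSegModel, build_single,
                     build_cgsnet, transfer_weights)
from .nn.tensor import Tensor
from .patch_sampler import PatchPair

EPS = 1e-6
NORM_MEAN = 0.5
NORM_STD = 0.25


# -------------------------------------------------------------------- losses
@dataclass
class LossConfig:
    focal_weight: float = 0.95
    dice_weight: float = 0.05
    focal_gamma: float = 2.0
    focal_alpha: float | None = None

    def __post_init__(self):
        if abs(self.focal_weight + self.dice_weight - 1.0) > 1e-9:
            raise ValueError("focal and dice weights must sum to 1")
        if self.focal_gamma < 0:
            raise ValueError("focal gamma must be >= 0")


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def focal_loss(probabilities, target_mask, gamma: float = 2.0,
               alpha: float | None = None) -> Tensor:
    """Mean of -(1 - p_t)^gamma log(p_t), optionally alpha-balanced."""
    p = _as_t(probabilities)
    t = _as_t(target_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = p.clip(EPS, 1.0 - EPS)
    pt = p * t + (1.0 - p) * (1.0 - t)
    loss = (1.0 - pt) ** gamma * (-pt.log())
    if alpha is not None:
        w = Tensor(alpha * t.data + (1.0 - alpha) * (1.0 - t.data))
        loss = loss * w
    return loss.mean()


def dice_loss(probabilities, target_mask, eps: float = EPS) -> Tensor:
    """Soft dice: 1 - (2 sum(p t) + eps) / (sum(p) + sum(t) + eps)."""
    p = _as_t(probabilities)
    t = _as_t(target_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = (p * t).sum()
    return 1.0 - (2.0 * inter + eps) / (p.sum() + t.sum() + eps)


def composite_loss(probabilities, target_mask,
                   cfg: LossConfig | None = None) -> Tensor:
    cfg = cfg or LossConfig()
    return (cfg.focal_weight * focal_loss(probabilities, target_mask,
                                          cfg.focal_gamma, cfg.focal_alpha)
            + cfg.dice_weight * dice_loss(probabilities, target_mask))


# ------------------------------------------------------------ regularization
@dataclass
class RegularizationConfig:
    l1: float = 0.0
    l2: float = 0.0
    dropout2d_rate: float = 0.15        # decoder + MCA only

    def __post_init__(self):
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("penalty weights must be >= 0")
        if not 0.0 <= self.dropout2d_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


def penalty(eligible_params, reg: RegularizationConfig) -> Tensor:
    """l1 * sum|w| + l2 * sum w^2 over the eligible parameters only.

    Eligible means: not pre-trained and not frozen at the start of the
    current phase; the caller supplies that set.
    """
    total = Tensor(np.zeros(()))
    if (reg.l1 == 0.0 and reg.l2 == 0.0) or not eligible_params:
        return total
    for p in eligible_params:
        if reg.l1:
            total = total + reg.l1 * p.abs().sum()
        if reg.l2:
            total = total + reg.l2 * (p * p).sum()
    return total


# -------------------------------------------------------------- augmentation
@dataclass
class AugmentationConfig:
    transpose: bool = True
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotate90: bool = True
    affine: bool = True
    affine_max_shift: float = 0.05      # fraction of the patch size
    affine_max_scale: float = 0.1
    gaussian_blur: bool = True
    blur_sigma_max: float = 1.0
    hsv_jitter: bool = True             # "hard" color augmentation
    hue_shift: float = 0.08
    sat_scale: float = 0.35
    val_scale: float = 0.25
    coarse_dropout: bool = True
    dropout_holes: int = 4
    dropout_size: int = 24
    p_geometric: float = 0.5
    p_color: float = 0.5


def augment_pair(pair: PatchPair, cfg: AugmentationConfig,
                 rng: np.random.Generator) -> PatchPair:
    """Apply one augmentation draw; geometry is shared by all four arrays."""
    det = pair.detail_image.copy()
    ctx = pair.context_image.copy()
    dmask = pair.detail_mask.copy()
    cmask = pair.context_mask.copy()

    def geo(fn):
        nonlocal det, ctx, dmask, cmask
        det, ctx, dmask, cmask = fn(det), fn(ctx), fn(dmask), fn(cmask)

    if cfg.transpose and rng.random() < cfg.p_geometric:
        geo(lambda a: np.ascontiguousarray(np.swapaxes(a, 0, 1)))
    if cfg.horizontal_flip and rng.random() < cfg.p_geometric:
        geo(lambda a: np.ascontiguousarray(a[:, ::-1]))
    if cfg.vertical_flip and rng.random() < cfg.p_geometric:
        geo(lambda a: np.ascontiguousarray(a[::-1]))
    if cfg.rotate90 and rng.random() < cfg.p_geometric:
        k = int(rng.integers(1, 4))
        geo(lambda a: np.ascontiguousarray(np.rot90(a, k)))
    if cfg.affine and rng.random() < cfg.p_geometric:
        h = det.shape[0]
        shift = rng.uniform(-cfg.affine_max_shift, cfg.affine_max_shift, 2) * h
        scale = 1.0 + rng.uniform(-cfg.affine_max_scale, cfg.affine_max_scale)
        # i = (o - center)/scale + center - shift
        center = (h - 1) / 2.0
        mat = np.eye(2) / scale
        off = center - center / scale - shift

        def warp(a, order):
            if a.ndim == 3:
                return np.stack([ndimage.affine_transform(
                    a[..., c].astype(np.float32), mat, offset=off, order=order,
                    mode="nearest") for c in range(a.shape[2])], axis=-1)
            return ndimage.affine_transform(a.astype(np.float32), mat,
                                            offset=off, order=order,
                                            mode="nearest")

        det = np.clip(warp(det, 1), 0, 255).astype(det.dtype)
        ctx = np.clip(warp(ctx, 1), 0, 255).astype(ctx.dtype)
        dmask = (warp(dmask, 0) > 0.5).astype(dmask.dtype)
        cmask = (warp(cmask, 0) > 0.5).astype(cmask.dtype)

    # color transforms: images only
    if cfg.hsv_jitter and rng.random() < cfg.p_color:
        from skimage import color as skcolor
        dh = rng.uniform(-cfg.hue_shift, cfg.hue_shift)
        ds = 1.0 + rng.uniform(-cfg.sat_scale, cfg.sat_scale)
        dv = 1.0 + rng.uniform(-cfg.val_scale, cfg.val_scale)

        def jitter(a):
            hsv = skcolor.rgb2hsv(a)
            hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
            hsv[..., 1] = np.clip(hsv[..., 1] * ds, 0, 1)
            hsv[..., 2] = np.clip(hsv[..., 2] * dv, 0, 1)
            return (skcolor.hsv2rgb(hsv) * 255).astype(a.dtype)

        det, ctx = jitter(det), jitter(ctx)
    if cfg.gaussian_blur and rng.random() < cfg.p_color:
        sigma = rng.uniform(0.1, cfg.blur_sigma_max)
        det = ndimage.gaussian_filter(det.astype(np.float32),
                                      (sigma, sigma, 0)).astype(det.dtype)
        ctx = ndimage.gaussian_filter(ctx.astype(np.float32),
                                      (sigma, sigma, 0)).astype(ctx.dtype)
    if cfg.coarse_dropout and rng.random() < cfg.p_color:
        h = det.shape[0]
        for _ in range(int(rng.integers(1, cfg.dropout_holes + 1))):
            y = int(rng.integers(0, h - cfg.dropout_size))
            x = int(rng.integers(0, h - cfg.dropout_size))
            det[y:y + cfg.dropout_size, x:x + cfg.dropout_size] = 0

    return PatchPair(detail_image=det, context_image=ctx, detail_mask=dmask,
                     context_mask=cmask, record=pair.record)


def normalize_image(img: np.ndarray) -> np.ndarray:
    """uint8 RGB -> normalized float32 CHW."""
    x = np.asarray(img, dtype=np.float32) / 255.0
    return ((x - NORM_MEAN) / NORM_STD).transpose(2, 0, 1)


# ----------------------------------------------------------------- schedules
@dataclass
class TrainingSchedule:
    single_frozen_epochs: int = 600
    single_total_epochs: int = 1000
    dual_mca_only_epochs: int = 300
    dual_joint_epochs: int = 300
    retrain_combined: bool = True
    batch_size: int = 16
    lr_encoder: float = 6e-5
    lr_decoder: float = 6e-4
    lr_mca: float = 6e-4
    scheduler_patience: int = 10

    def __post_init__(self):
        if self.single_frozen_epochs > self.single_total_epochs:
            raise ValueError("frozen epochs exceed total epochs")
        for v in (self.single_frozen_epochs, self.single_total_epochs,
                  self.dual_mca_only_epochs, self.dual_joint_epochs):
            if v < 0:
                raise ValueError("epoch counts must be >= 0")


@dataclass
class SegDataset:
    """Arrays ready for training: images (N,3,H,W) float32, masks (N,H,W)."""

    train_x: np.ndarray
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    train_ctx: np.ndarray | None = None   # dual mode only
    val_ctx: np.ndarray | None = None

    def union(self) -> "SegDataset":
        """Train+val merged (used for the retraining stage); val kept for
        bookkeeping but ignored as a selection signal."""
        cat = lambda a, b: np.concatenate([a, b], axis=0)
        return SegDataset(
            train_x=cat(self.train_x, self.val_x),
            train_y=cat(self.train_y, self.val_y),
            val_x=self.val_x, val_y=self.val_y,
            train_ctx=(cat(self.train_ctx, self.val_ctx)
                       if self.train_ctx is not None else None),
            val_ctx=self.val_ctx)


def _downsample_image(chw: np.ndarray, factor: int) -> np.ndarray:
    c, h, w = chw.shape
    return chw.reshape(c, h // factor, factor, w // factor, factor).mean(axis=(2, 4))


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    h, w = mask.shape
    blocks = mask.reshape(h // factor, factor, w // factor, factor)
    return (blocks.mean(axis=(1, 3)) >= 0.5).astype(np.float32)


def dataset_from_pairs(pairs_by_split: dict[str, list[PatchPair]],
                       mode: str = "single_detail",
                       downsample: int = 1) -> SegDataset:
    """Assemble normalized training arrays from extracted patch pairs.

    ``downsample`` reduces the spatial resolution by an integer factor (the
    pairing geometry is scale-invariant), keeping CPU runs tractable.
    """
    def build(split):
        xs, ys, cs = [], [], []
        for pair in pairs_by_split.get(split, []):
            det = normalize_image(pair.detail_image)
            ctx = normalize_image(pair.context_image)
            if mode == "single_context":
                x, y = ctx, pair.context_mask.astype(np.float32)
            else:
                x, y = det, pair.detail_mask.astype(np.float32)
            if downsample > 1:
                x = _downsample_image(x, downsample)
                ctx = _downsample_image(ctx, downsample)
                y = _downsample_mask(y, downsample)
            xs.append(x)
            ys.append(y)
            cs.append(ctx)
        if not xs:
            raise ValueError(f"empty split '{split}'")
        return (np.stack(xs).astype(np.float32), np.stack(ys),
                np.stack(cs).astype(np.float32))

    tx, ty, tc = build("train")
    vx, vy, vc = build("val")
    dual = mode == "dual"
    return SegDataset(train_x=tx, train_y=ty, val_x=vx, val_y=vy,
                      train_ctx=tc if dual else None,
                      val_ctx=vc if dual else None)


# -------------------------------------------------------------- train loops
def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def _forward(model, x, ctx=None):
    if ctx is None:
        return model(Tensor(x))
    return model(Tensor(x), Tensor(ctx))


def _eval_loss(model, x, y, ctx, loss_cfg, batch_size):
    model.eval()
    tot, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        out = _forward(model, x[i:i + batch_size],
                       None if ctx is None else ctx[i:i + batch_size])
        tot += composite_loss(out, y[i:i + batch_size], loss_cfg).item() * len(
            x[i:i + batch_size])
        n += len(x[i:i + batch_size])
    model.train()
    return tot / max(n, 1)


def optimizer_groups(model, schedule: TrainingSchedule):
    """Four Adam groups (detail enc, context enc, decoder, MCA) and the
    three schedulers (encoders, decoder, MCA) for a dual model; two groups
    and one scheduler set for a single model."""
    if isinstance(model, DualSegModel):
        det = model.encoder_detail.parameters()
        ctx = model.encoder_context.parameters()
        dec = model.decoder.parameters()
        mca = [p for blk in model.mca_blocks() for p in blk.parameters()]
        groups = [
            {"params": det, "lr": schedule.lr_encoder},
            {"params": ctx, "lr": schedule.lr_encoder},
            {"params": dec, "lr": schedule.lr_decoder},
            {"params": mca, "lr": schedule.lr_mca},
        ]
        opt = nn.Adam(groups)
        scheds = [nn.ReduceLROnPlateau(opt, patience=schedule.scheduler_patience,
                                       group_indices=[0, 1]),
                  nn.ReduceLROnPlateau(opt, patience=schedule.scheduler_patience,
                                       group_indices=[2]),
                  nn.ReduceLROnPlateau(opt, patience=schedule.scheduler_patience,
                                       group_indices=[3])]
    else:
        groups = [
            {"params": model.encoder.parameters(), "lr": schedule.lr_encoder},
            {"params": model.decoder.parameters(), "lr": schedule.lr_decoder},
        ]
        opt = nn.Adam(groups)
        scheds = [nn.ReduceLROnPlateau(opt, patience=schedule.scheduler_patience,
                                       group_indices=[0]),
                  nn.ReduceLROnPlateau(opt, patience=schedule.scheduler_patience,
                                       group_indices=[1])]
    all_group_params = [id(p) for g in groups for p in g["params"]]
    model_params = [id(p) for p in model.parameters()]
    if sorted(all_group_params) != sorted(model_params):
        raise AssertionError("optimizer groups do not partition the parameters")
    return opt, scheds


def _run_epochs(model, dataset, opt, scheds, n_epochs, loss_cfg, reg,
                eligible, rng, history, schedule, phase):
    for _ in range(n_epochs):
        tr_loss, n_seen = 0.0, 0
        for idx in _epoch_batches(len(dataset.train_x), schedule.batch_size, rng):
            x = dataset.train_x[idx]
            y = dataset.train_y[idx]
            ctx = dataset.train_ctx[idx] if dataset.train_ctx is not None else None
            out = _forward(model, x, ctx)
            loss = composite_loss(out, y, loss_cfg)
            if reg is not None:
                loss = loss + penalty(eligible, reg)
            model.zero_grad()
            loss.backward()
            opt.step()
            tr_loss += loss.item() * len(idx)
            n_seen += len(idx)
        val_loss = _eval_loss(model, dataset.val_x, dataset.val_y,
                              dataset.val_ctx, loss_cfg, schedule.batch_size)
        for s in scheds:
            s.step(val_loss)
        history.append({"phase": phase, "epoch": len(history) + 1,
                        "train_loss": tr_loss / max(n_seen, 1),
                        "val_loss": val_loss,
                        "lrs": [g["lr"] for g in opt.groups]})
    return history


def train_single(dataset: SegDataset, model_config: ModelConfig,
                 schedule: TrainingSchedule | None = None, seed: int = 0,
                 loss_cfg: LossConfig | None = None,
                 reg: RegularizationConfig | None = None):
    """Single-model pre-training: encoder frozen, then full fine-tune."""
    schedule = schedule or TrainingSchedule()
    loss_cfg = loss_cfg or LossConfig()
    if len(dataset.train_x) == 0 or len(dataset.val_x) == 0:
        raise ValueError("empty training or validation split")
    model = build_single(model_config, seed=seed)
    nn.seed_dropout(model, seed)
    rng = np.random.default_rng((seed, 1))
    opt, scheds = optimizer_groups(model, schedule)
    history: list[dict] = []
    pretrained = model_config.encoder.pretrained_source is not None
    # eligible for weight penalties: not pretrained, not frozen at phase start
    eligible = model.decoder.parameters()

    model.encoder.freeze()
    _run_epochs(model, dataset, opt, scheds, schedule.single_frozen_epochs,
                loss_cfg, reg, eligible, rng, history, schedule, "frozen_encoder")
    model.encoder.unfreeze()
    if not pretrained:
        eligible = eligible + model.encoder.parameters()
    _run_epochs(model, dataset, opt, scheds,
                schedule.single_total_epochs - schedule.single_frozen_epochs,
                loss_cfg, reg, eligible, rng, history, schedule, "full")
    best = (int(np.argmin([h["val_loss"] for h in history])) + 1) if history else 0
    return model, best, history


def train_dual(dataset: SegDataset, singles, dual_config: ModelConfig,
               schedule: TrainingSchedule | None = None, seed: int = 0,
               loss_cfg: LossConfig | None = None,
               reg: RegularizationConfig | None = None):
    """Dual-model training: transfer, MCA-only phase, then joint phase."""
    schedule = schedule or TrainingSchedule()
    loss_cfg = loss_cfg or LossConfig()
    single_detail, single_context = singles
    if dataset.train_ctx is None:
        raise ValueError("dual training requires context inputs")
    model = build_cgsnet(dual_config, seed=seed)
    transfer_weights(single_detail, single_context, model)
    nn.seed_dropout(model, seed)
    rng = np.random.default_rng((seed, 2))
    opt, scheds = optimizer_groups(model, schedule)
    history: list[dict] = []
    mca_params = [p for blk in model.mca_blocks() for p in blk.parameters()]

    model.encoder_detail.freeze()
    model.encoder_context.freeze()
    model.decoder.freeze()
    _run_epochs(model, dataset, opt, scheds, schedule.dual_mca_only_epochs,
                loss_cfg, reg, mca_params, rng, history, schedule, "mca_only")
    model.encoder_detail.unfreeze()
    model.encoder_context.unfreeze()
    model.decoder.unfreeze()
    _run_epochs(model, dataset, opt, scheds, schedule.dual_joint_epochs,
                loss_cfg, reg, mca_params, rng, history, schedule, "joint")
    best = (int(np.argmin([h["val_loss"] for h in history])) + 1) if history else 0
    return model, best, history


def retrain_combined(model_config: ModelConfig, dataset: SegDataset,
                     best_val_epoch: int, schedule: TrainingSchedule | None = None,
                     seed: int = 0, singles=None,
                     loss_cfg: LossConfig | None = None,
                     reg: RegularizationConfig | None = None):
    """Fresh run of the same schedule on train+val, stopped at the epoch of
    the lowest validation loss from the selection run."""
    if best_val_epoch < 1:
        raise ValueError("best_val_epoch must be >= 1")
    schedule = schedule or TrainingSchedule()
    union = dataset.union()
    if model_config.mode == "dual":
        total = schedule.dual_mca_only_epochs + schedule.dual_joint_epochs
        trunc = replace(
            schedule,
            dual_mca_only_epochs=min(best_val_epoch, schedule.dual_mca_only_epochs),
            dual_joint_epochs=max(0, min(best_val_epoch, total)
                                  - schedule.dual_mca_only_epochs))
        model, _, history = train_dual(union, singles, model_config, trunc,
                                       seed, loss_cfg, reg)
    else:
        total = schedule.single_total_epochs
        trunc = replace(
            schedule,
            single_frozen_epochs=min(best_val_epoch, schedule.single_frozen_epochs),
            single_total_epochs=min(best_val_epoch, total))
        model, _, history = train_single(union, model_config, trunc, seed,
                                         loss_cfg, reg)
    return model, history
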