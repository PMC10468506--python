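"""Losses, augmentation, patch sampling, cross-validation and the training loop.

The optimization recipe follows common practice for medical image
segmentation: AdamW (learning rate 1e-4, decoupled weight decay 0.01)
minimizing the sum of soft-Dice loss and cross-entropy, with the loss
additionally evaluated at the decoder's lower resolutions (multi-scale deep
supervision, level weights halving and normalized to sum 1). Training stops
early once the validation loss has not improved for a fixed number of epochs
(default 30) and the best-validation weights are restored.

Augmentation covers the usual MRI families — flips, affine, ghosting,
Gaussian noise, blurring, bias field, gamma — with spatial transforms applied
jointly to image and mask (nearest-neighbour for the mask) and intensity
transforms to the images only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform, gaussian_filter

from .models import NetworkOutput
from .nn import AdamW, Tensor, no_grad

__all__ = [
    "TrainConfig", "AugmentConfig", "FoldSplit", "Fold", "TrainingCase",
    "TrainResult", "EarlyStopper", "make_folds", "dice_ce_loss",
    "multiscale_loss", "augment", "sample_patch", "train_model",
    "cases_from_phantom",
]


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class AugmentConfig:
    p_flip: float = 0.5           # per eligible axis
    flip_axes: tuple[int, ...] = (0, 1, 2)
    p_affine: float = 0.3
    max_rotation_deg: float = 10.0   # about the slice axis
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_ghosting: float = 0.2
    ghost_strength: float = 0.3
    p_noise: float = 0.3
    noise_sd: float = 0.05
    p_blur: float = 0.2
    blur_sigma: float = 1.0
    p_bias: float = 0.2
    bias_amplitude: float = 0.3
    p_gamma: float = 0.3
    log_gamma_sd: float = 0.2

    @staticmethod
    def identity() -> "AugmentConfig":
        return AugmentConfig(p_flip=0, p_affine=0, p_ghosting=0, p_noise=0,
                             p_blur=0, p_bias=0, p_gamma=0)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 1
    patch_size: tuple[int, int, int] = (256, 256, 32)
    early_stop_patience_epochs: int = 30
    max_epochs: int = 1000
    steps_per_epoch: int = 10
    seed: int = 0
    multiscale_weights: tuple[float, ...] | None = None  # None -> halving, normalized
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    stop_at_train_dice: float | None = None  # optional convergence target

    def validate(self) -> None:
        if self.early_stop_patience_epochs < 1:
            raise ValueError("patience must be >= 1")
        if self.multiscale_weights is not None:
            w = np.asarray(self.multiscale_weights, dtype=float)
            if (w < 0).any():
                raise ValueError("multiscale weights must be nonnegative")


@dataclass(frozen=True)
class Fold:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]


@dataclass(frozen=True)
class FoldSplit:
    k: int
    folds: tuple[Fold, ...]


@dataclass
class TrainingCase:
    case_id: str
    channels: np.ndarray  # (C, rows, cols, slices)
    mask: np.ndarray      # (rows, cols, slices), labels in {0,1}


@dataclass
class TrainResult:
    history: pd.DataFrame     # columns: epoch, train_loss, val_loss, train_dice
    best_epoch: int           # 1-based epoch whose weights were restored
    stopped_epoch: int


# --------------------------------------------------------------------------
# folds


def make_folds(case_ids, k: int = 5, seed: int = 0) -> FoldSplit:
    """K-fold split; per fold the non-test cases are divided 80/20 into
    train/validation (validation size = max(1, round(0.2 n)))."""
    ids = list(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} cases, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_folds = [list(a) for a in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    for i in range(k):
        test = [str(x) for x in test_folds[i]]
        rest = [x for x in order if x not in test]
        rest = [rest[j] for j in rng.permutation(len(rest))]
        n_val = max(1, round(0.2 * len(rest)))
        folds.append(Fold(train=tuple(rest[n_val:]), val=tuple(rest[:n_val]),
                          test=tuple(test)))
    return FoldSplit(k=k, folds=tuple(folds))


def cases_from_phantom(case, case_id: str, include_t2: bool = False
                       ) -> list[TrainingCase]:
    """Stage-2 training samples from a phantom: one per breast side, with
    per-side z-normalized (pre, subtraction[, T2]) channels and the cropped
    FGT mask as target. Both sides of a case enter training as independent
    samples."""
    from .pipeline import split_sides, subtraction_image, znormalize

    sub = subtraction_image(case.post_t1, case.pre_t1)
    channels = [case.pre_t1, sub] + ([case.t2] if include_t2 else [])
    out = []
    for side in split_sides(case.breast_mask, channels):
        if side is None:
            continue
        ch = np.stack([
            znormalize(c).values if c.values.std() > 0
            else np.zeros(c.shape, dtype=np.float32)
            for c in side.channels])
        sl = tuple(slice(a, b) for a, b in side.crop_box)
        out.append(TrainingCase(case_id=f"{case_id}_{side.side}", channels=ch,
                                mask=case.fgt_mask.labels[sl]))
    return out


# --------------------------------------------------------------------------
# losses


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    # target: (N, ...) int -> (N, K, ...)
    oh = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float32)
    for c in range(n_classes):
        oh[:, c] = target == c
    return oh


def dice_ce_loss(logits: Tensor, target: np.ndarray, smooth: float = 1e-5) -> Tensor:
    """Sum of soft-Dice loss (foreground classes) and voxel-mean cross-entropy."""
    if logits.shape[0] != target.shape[0] or logits.shape[2:] != target.shape[1:]:
        raise ValueError(f"logits {logits.shape} and target {target.shape} misaligned")
    n_classes = logits.shape[1]
    oh = _one_hot(target.astype(np.int64), n_classes)
    log_sm = logits.log_softmax(axis=1)
    n_vox = int(np.prod(target.shape))
    ce = -(log_sm * Tensor(oh)).sum() * (1.0 / n_vox)
    probs = logits.softmax(axis=1)
    dice_terms = []
    for c in range(1, n_classes):
        p = probs[:, c]
        t = Tensor(oh[:, c])
        inter = (p * t).sum()
        denom = p.sum() + t.sum()
        dice_terms.append(1.0 - (inter * 2.0 + smooth) / (denom + smooth))
    dice = dice_terms[0]
    for term in dice_terms[1:]:
        dice = dice + term
    dice = dice * (1.0 / len(dice_terms))
    return dice + ce


def _downsample_mask(mask: np.ndarray, factors) -> np.ndarray:
    """Nearest-neighbour downsampling: take the center voxel of each block."""
    sl = tuple([slice(None)] + [slice(f // 2, None, f) for f in factors])
    return mask[sl]


def multiscale_loss(output: NetworkOutput, target: np.ndarray,
                    weights: tuple[float, ...] | None = None) -> Tensor:
    """Weighted sum of Dice+CE losses over the main and auxiliary outputs.

    Auxiliary targets are the mask, zero-padded like the network input and
    downsampled (nearest-neighbour) by each auxiliary factor. Default weights
    halve per level and are normalized to sum 1."""
    n_heads = 1 + len(output.aux_logits)
    if weights is None:
        w = np.array([0.5 ** i for i in range(n_heads)])
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n_heads:
            raise ValueError(f"{len(w)} weights for {n_heads} output heads")
    if w.sum() <= 0:
        raise ValueError("at least one multiscale weight must be positive")
    w = w / w.sum()
    loss = dice_ce_loss(output.main_logits, target) * float(w[0])
    if output.aux_logits:
        padded = np.pad(target, [(0, 0)] + [list(p) for p in output.pad])
        for wi, aux, factors in zip(w[1:], output.aux_logits, output.aux_factors):
            if wi == 0:
                continue
            tgt = _downsample_mask(padded, factors)
            loss = loss + dice_ce_loss(aux, tgt) * float(wi)
    return loss


# --------------------------------------------------------------------------
# augmentation


def _affine_pair(channels, mask, rng, cfg: AugmentConfig):
    theta = math.radians(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    scale = rng.uniform(*cfg.scale_range)
    c, s = math.cos(theta), math.sin(theta)
    mat = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]) / scale
    center = (np.array(mask.shape) - 1) / 2.0
    offset = center - mat @ center
    out_ch = np.stack([affine_transform(ch, mat, offset=offset, order=1,
                                        mode="constant", cval=ch.min())
                       for ch in channels])
    out_mask = affine_transform(mask, mat, offset=offset, order=0,
                                mode="constant", cval=0)
    return out_ch.astype(np.float32), out_mask.astype(mask.dtype)


def _ghosting(img: np.ndarray, rng, strength: float) -> np.ndarray:
    axis = int(rng.integers(0, 3))
    n_ghosts = int(rng.integers(2, 6))
    k = np.fft.fft(img, axis=axis)
    idx = [slice(None)] * 3
    sel = np.arange(k.shape[axis])
    keep = (sel % n_ghosts == 0) & (sel != 0)  # spare the DC line
    idx[axis] = keep
    k[tuple(idx)] *= (1.0 - strength)
    return np.real(np.fft.ifft(k, axis=axis)).astype(np.float32)


def _bias(img: np.ndarray, rng, amplitude: float) -> np.ndarray:
    g = gaussian_filter(rng.standard_normal(img.shape),
                        sigma=np.maximum(np.array(img.shape) / 6.0, 1.0))
    peak = np.abs(g).max()
    if peak > 0:
        g = g / peak
    return (img * (1.0 + amplitude * g)).astype(np.float32)


def augment(channels: np.ndarray, mask: np.ndarray, seed: int,
            config: AugmentConfig | None = None):
    """Random augmentation of one (channels, mask) sample; deterministic per seed.

    Spatial transforms hit image and mask identically (mask interpolated
    nearest-neighbour); intensity transforms hit the images only. Returns new
    arrays; the mask stays binary."""
    cfg = config if config is not None else AugmentConfig()
    rng = np.random.default_rng(seed)
    ch = np.asarray(channels, dtype=np.float32).copy()
    mk = np.asarray(mask).copy()
    if ch.shape[1:] != mk.shape:
        raise ValueError("channels and mask spatial shapes differ")

    for axis in cfg.flip_axes:
        if rng.random() < cfg.p_flip:
            ch = np.flip(ch, axis=axis + 1).copy()
            mk = np.flip(mk, axis=axis).copy()
    if rng.random() < cfg.p_affine:
        ch, mk = _affine_pair(ch, mk, rng, cfg)
    if rng.random() < cfg.p_ghosting:
        ch = np.stack([_ghosting(c, rng, cfg.ghost_strength) for c in ch])
    if rng.random() < cfg.p_noise:
        ch = ch + rng.normal(0, cfg.noise_sd, ch.shape).astype(np.float32)
    if rng.random() < cfg.p_blur:
        sigma = rng.uniform(0.3, cfg.blur_sigma)
        ch = np.stack([gaussian_filter(c, sigma=sigma) for c in ch])
    if rng.random() < cfg.p_bias:
        ch = np.stack([_bias(c, rng, cfg.bias_amplitude) for c in ch])
    if rng.random() < cfg.p_gamma:
        gamma = math.exp(rng.normal(0, cfg.log_gamma_sd))
        lo, hi = ch.min(), ch.max()
        if hi > lo:
            ch = ((ch - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
    return ch.astype(np.float32), mk


# --------------------------------------------------------------------------
# patch sampling


def _pad_to_at_least(arr: np.ndarray, target, spatial_offset: int):
    pads = [(0, 0)] * spatial_offset
    for ax, t in enumerate(target):
        n = arr.shape[spatial_offset + ax]
        extra = max(0, t - n)
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(arr, pads)


def sample_patch(channels: np.ndarray, mask: np.ndarray,
                 patch_size: tuple[int, int, int], rng) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random patch fully inside the (zero-padded) sample."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    ch = _pad_to_at_least(np.asarray(channels), patch_size, 1)
    mk = _pad_to_at_least(np.asarray(mask), patch_size, 0)
    starts = [int(rng.integers(0, n - p + 1))
              for n, p in zip(mk.shape, patch_size)]
    sl = tuple(slice(s, s + p) for s, p in zip(starts, patch_size))
    return ch[(slice(None),) + sl].copy(), mk[sl].copy()


# --------------------------------------------------------------------------
# early stopping and the loop


class EarlyStopper:
    """Stop when the validation loss has not improved for `patience` epochs;
    tracks the arg-min epoch (1-based)."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = math.inf
        self.best_epoch = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record epoch's validation loss; return True if training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
        return (epoch - self.best_epoch) >= self.patience


def _foreground_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(pred == 1, truth == 1).sum()
    sizes = (pred == 1).sum() + (truth == 1).sum()
    return 1.0 if sizes == 0 else 2.0 * inter / sizes


def train_model(network, cases: list[TrainingCase], fold: FoldSplit,
                fold_index: int, config: TrainConfig) -> TrainResult:
    """Train `network` on one fold; restores the best-validation weights.

    Raises RuntimeError on divergence (non-finite loss)."""
    config.validate()
    f = fold.folds[fold_index]
    by_id = {c.case_id: c for c in cases}
    train_cases = [by_id[i] for i in f.train]
    val_cases = [by_id[i] for i in f.val]
    if not train_cases or not val_cases:
        raise ValueError("fold has empty train or validation set")

    rng = np.random.default_rng(config.seed)
    opt = AdamW(network.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    stopper = EarlyStopper(config.early_stop_patience_epochs)
    best_state = network.state_dict()
    rows = []
    stopped = config.max_epochs
    for epoch in range(1, config.max_epochs + 1):
        epoch_losses = []
        train_dice = math.nan
        for _ in range(config.steps_per_epoch):
            chs, mks = [], []
            for _ in range(config.batch_size):
                case = train_cases[int(rng.integers(0, len(train_cases)))]
                ch, mk = sample_patch(case.channels, case.mask,
                                      config.patch_size, rng)
                if config.augment is not None:
                    ch, mk = augment(ch, mk, int(rng.integers(0, 2 ** 31)),
                                     config.augment)
                chs.append(ch)
                mks.append(mk)
            batch = np.stack(chs)
            target = np.stack(mks).astype(np.int64)
            out = network(batch)
            loss = multiscale_loss(out, target, config.multiscale_weights)
            lv = float(loss.data)
            if not math.isfinite(lv):
                raise RuntimeError(f"training diverged: loss={lv} at epoch {epoch}")
            network.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(lv)
        pred = out.main_logits.data.argmax(axis=1)
        train_dice = _foreground_dice(pred, target)

        with no_grad():
            val_losses = []
            for case in val_cases:
                ch, mk = sample_patch(case.channels, case.mask, config.patch_size,
                                      np.random.default_rng(0))
                vout = network(ch[None])
                val_losses.append(float(multiscale_loss(
                    vout, mk[None].astype(np.int64),
                    config.multiscale_weights).data))
        val_loss = float(np.mean(val_losses))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                     "val_loss": val_loss, "train_dice": train_dice})
        if val_loss < stopper.best:
            best_state = network.state_dict()
        if stopper.update(epoch, val_loss):
            stopped = epoch
            break
        if (config.stop_at_train_dice is not None
                and train_dice >= config.stop_at_train_dice):
            stopped = epoch
            best_state = network.state_dict()
            stopper.best_epoch = epoch
            break
    else:
        stopped = config.max_epochs

    network.load_state_dict(best_state)
    return TrainResult(history=pd.DataFrame(rows),
                       best_epoch=stopper.best_epoch, stopped_epoch=stopped)
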