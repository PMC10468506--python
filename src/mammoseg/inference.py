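"""Sliding-window prediction, flip test-time augmentation, majority-vote
ensembling and the two-stage pipeline orchestration.

Inference tiles each (cropped) breast side with overlapping patches (default
50% overlap); the last window on each axis is shifted to end-align with the
volume so every voxel is covered, and overlapping softmax probabilities are
averaged with uniform weights. Test-time augmentation averages predictions
over mirrored copies of the input — by default all 8 flip combinations, which
is deterministic and a superset of random flipping; a seeded random subset is
available. Cross-fold ensembling takes a per-voxel majority vote over the
models' hard (argmax) masks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .phantom import PhantomCase
from .pipeline import (DEFAULT_MARGIN, CroppedSide, paste_into, split_sides,
                       stack_channels, subtraction_image, znormalize)
from .volume import MaskVolume, Volume3D
from .nn import no_grad

__all__ = ["ProbabilityMap", "InferenceSettings", "sliding_window_predict",
           "tta_predict", "majority_vote", "segment_case", "window_starts"]


@dataclass
class ProbabilityMap:
    """Per-class probabilities, class axis first, aligned to the input grid."""

    probs: np.ndarray  # (K, rows, cols, slices)

    def __post_init__(self):
        p = self.probs
        if p.ndim != 4:
            raise ValueError("ProbabilityMap needs a (K, rows, cols, slices) array")
        if p.min() < -1e-6 or p.max() > 1 + 1e-6:
            raise ValueError("probabilities outside [0, 1]")
        sums = p.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-5:
            raise ValueError("per-voxel class probabilities must sum to 1")

    def argmax_mask(self, spacing_mm, foreground_class: int = 1) -> MaskVolume:
        lab = (self.probs.argmax(axis=0) == foreground_class).astype(np.uint8)
        return MaskVolume(lab, spacing_mm)


@dataclass(frozen=True)
class InferenceSettings:
    patch_size: tuple[int, int, int] = (256, 256, 32)
    overlap: float = 0.5
    tta: str | tuple = "all"      # "all" | "off" | ("random", k, seed)
    margin_voxels: tuple[int, int, int] = DEFAULT_MARGIN
    include_t2: bool = False
    restrict_to_breast: bool = True
    vote: str = "majority"        # "majority" | "mean_probability"


def window_starts(length: int, patch: int, overlap: float) -> list[int]:
    """Start indices along one axis; stride = patch*(1-overlap), last window
    end-aligned so the volume edge is always covered."""
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    if length <= patch:
        return [0]
    stride = max(1, int(round(patch * (1.0 - overlap))))
    starts = list(range(0, length - patch + 1, stride))
    if starts[-1] != length - patch:
        starts.append(length - patch)
    return starts


def _pad_to_patch(channels: np.ndarray, patch):
    pads = [(0, 0)]
    for ax, p in enumerate(patch):
        extra = max(0, p - channels.shape[1 + ax])
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(channels, pads), pads[1:]


def sliding_window_predict(network, channels: np.ndarray,
                           patch_size=(256, 256, 32), overlap: float = 0.5
                           ) -> ProbabilityMap:
    """Tile the volume, average softmax probabilities over window overlaps."""
    channels = np.asarray(channels, dtype=np.float32)
    if channels.ndim != 4:
        raise ValueError("channels must be (C, rows, cols, slices)")
    orig = channels.shape[1:]
    x, pads = _pad_to_patch(channels, patch_size)
    shape = x.shape[1:]
    n_classes = network.config.n_classes
    acc = np.zeros((n_classes,) + shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.float64)
    axes_starts = [window_starts(n, p, overlap) for n, p in zip(shape, patch_size)]
    with no_grad():
        for s0, s1, s2 in itertools.product(*axes_starts):
            sl = (slice(None), slice(s0, s0 + patch_size[0]),
                  slice(s1, s1 + patch_size[1]), slice(s2, s2 + patch_size[2]))
            out = network(x[sl][None])
            z = out.main_logits.data[0]
            z = z - z.max(axis=0, keepdims=True)
            e = np.exp(z)
            acc[sl] += e / e.sum(axis=0, keepdims=True)
            cnt[sl[1:]] += 1.0
    assert cnt.min() >= 1, "internal error: sliding window left voxels uncovered"
    probs = acc / cnt
    crop = tuple(slice(p0, p0 + n) for (p0, _), n in zip(pads, orig))
    return ProbabilityMap(probs[(slice(None),) + crop].astype(np.float32))


def _flip_combos(policy):
    if policy == "all":
        return [c for r in range(4) for c in itertools.combinations((0, 1, 2), r)]
    if policy == "off" or policy == ("off",):
        return [()]
    if isinstance(policy, tuple) and policy and policy[0] == "random":
        _, k, seed = policy
        rng = np.random.default_rng(seed)
        combos = [c for r in range(4) for c in itertools.combinations((0, 1, 2), r)]
        pick = rng.choice(len(combos), size=min(k, len(combos)), replace=False)
        return [combos[i] for i in sorted(pick)]
    raise ValueError(f"unknown TTA policy {policy!r}")


def tta_predict(network, channels: np.ndarray, patch_size=(256, 256, 32),
                overlap: float = 0.5, policy="all") -> ProbabilityMap:
    """Average sliding-window predictions over mirrored copies of the input."""
    combos = _flip_combos(policy)
    acc = None
    for axes in combos:
        sp_axes = tuple(a + 1 for a in axes)
        x = np.flip(channels, axis=sp_axes) if axes else channels
        pm = sliding_window_predict(network, np.ascontiguousarray(x),
                                    patch_size, overlap)
        p = np.flip(pm.probs, axis=sp_axes) if axes else pm.probs
        acc = p.astype(np.float64) if acc is None else acc + p
    return ProbabilityMap((acc / len(combos)).astype(np.float32))


def majority_vote(masks: list[MaskVolume], tie_break: str | None = None) -> MaskVolume:
    """Per-voxel vote: foreground iff more than half the masks agree.

    Even counts are rejected unless `tie_break` is 'background' or
    'foreground'."""
    if not masks:
        raise ValueError("majority_vote needs at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"masks are not aligned: {shapes}")
    n = len(masks)
    if n % 2 == 0 and tie_break is None:
        raise ValueError("even number of masks: ties undefined; pass tie_break=")
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += m.labels
    out = votes * 2 > n
    if n % 2 == 0 and tie_break == "foreground":
        out = votes * 2 >= n
    return MaskVolume(out.astype(np.uint8), masks[0].spacing_mm)


def _safe_znorm(v: Volume3D) -> Volume3D:
    try:
        return znormalize(v)
    except ValueError:
        return Volume3D(np.zeros(v.shape, dtype=np.float32), v.spacing_mm)


def segment_case(case: PhantomCase, stage1_source, stage2_models,
                 settings: InferenceSettings = InferenceSettings()
                 ) -> tuple[MaskVolume, MaskVolume]:
    """Run the two-stage pipeline on one case; returns (fgt_mask, breast_mask).

    `stage1_source` is either a ready whole-breast MaskVolume (e.g. ground
    truth) or a stage-1 network applied to the full (pre[, T2]) volume.
    Stage 2 crops each breast side, z-normalizes the (pre, subtraction[, T2])
    channels per side, predicts with each model (sliding window + TTA), takes
    per-model argmax masks and combines them by majority vote before pasting
    the sides back into the full grid."""
    if not stage2_models:
        raise ValueError("need at least one stage-2 model")
    spacing = case.pre_t1.spacing_mm

    if isinstance(stage1_source, MaskVolume):
        breast = stage1_source
    else:
        full_channels = [_safe_znorm(case.pre_t1)]
        if settings.include_t2:
            full_channels.append(_safe_znorm(case.t2))
        stacked = np.stack([c.values for c in full_channels])
        pm = tta_predict(stage1_source, stacked, settings.patch_size,
                         settings.overlap, settings.tta)
        breast = pm.argmax_mask(spacing)

    fgt_full = np.zeros(case.pre_t1.shape, dtype=np.uint8)
    if not breast.labels.any():
        warnings.warn("stage-1 breast mask is empty; returning empty FGT mask",
                      stacklevel=2)
        return MaskVolume(fgt_full, spacing), breast

    sub = subtraction_image(case.post_t1, case.pre_t1)
    channels = [case.pre_t1, sub] + ([case.t2] if settings.include_t2 else [])
    sides = split_sides(breast, channels, settings.margin_voxels)
    for side in sides:
        if side is None:
            continue
        normed = CroppedSide(channels=[_safe_znorm(c) for c in side.channels],
                             side=side.side, crop_box=side.crop_box)
        stacked = stack_channels(normed)
        per_model = []
        mean_probs = None
        for model in stage2_models:
            pm = tta_predict(model, stacked, settings.patch_size,
                             settings.overlap, settings.tta)
            per_model.append(pm.argmax_mask(spacing))
            mean_probs = (pm.probs.astype(np.float64) if mean_probs is None
                          else mean_probs + pm.probs)
        if settings.vote == "mean_probability":
            side_mask = (np.argmax(mean_probs, axis=0) == 1).astype(np.uint8)
        else:
            side_mask = majority_vote(
                per_model,
                tie_break="background" if len(per_model) % 2 == 0 else None).labels
        paste_into(fgt_full, side_mask, side.crop_box)

    if settings.restrict_to_breast:
        fgt_full &= breast.labels
    return MaskVolume(fgt_full, spacing), breast
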