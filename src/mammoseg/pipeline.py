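"""Preprocessing for the two-stage segmentation pipeline.

Stage 1 segments the whole breast on the full volume; stage 2 segments FGT on
per-side crops. This module holds the glue between the stages: z-score
normalization, subtraction images, the left/right laterality split with
per-side bounding-box crops, and channel stacking.

Conventions: crop boxes are 0-based, half-open ``(start, stop)`` ranges per
axis; the lateral midline is half the column axis; side "right" is the
low-column half (columns run patient-right to patient-left, see
:mod:`mammoseg.volume`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .volume import MaskVolume, Volume3D

__all__ = ["CroppedSide", "znormalize", "subtraction_image", "split_sides",
           "stack_channels", "unstack_channels", "crop_to_box", "paste_into",
           "crop_box_to_json", "crop_box_from_json", "DEFAULT_MARGIN"]

CropBox = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

#: 8 voxels of in-plane margin around the breast bounding box, none along slices
DEFAULT_MARGIN = (8, 8, 0)


@dataclass
class CroppedSide:
    """One breast's multi-channel crop plus where it came from."""

    channels: list[Volume3D]
    side: str  # "left" | "right"
    crop_box: CropBox

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if len(self.channels) < 1:
            raise ValueError("CroppedSide needs at least one channel")
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        box_shape = tuple(b - a for a, b in self.crop_box)
        if box_shape != self.channels[0].shape:
            raise ValueError(f"crop_box extent {box_shape} != channel shape "
                             f"{self.channels[0].shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape


def znormalize(v: Volume3D) -> Volume3D:
    """Z-score normalization: zero mean, unit standard deviation."""
    vals = v.values.astype(np.float64)
    sd = vals.std()
    if sd == 0:
        raise ValueError("cannot z-normalize a constant volume (SD = 0)")
    out = (vals - vals.mean()) / sd
    return Volume3D(out.astype(np.float32), v.spacing_mm)


def subtraction_image(post: Volume3D, pre: Volume3D) -> Volume3D:
    """Contrast-enhanced subtraction: post minus pre, voxelwise."""
    if post.shape != pre.shape:
        raise ValueError(f"shape mismatch: post {post.shape} vs pre {pre.shape}")
    return Volume3D(post.values.astype(np.float32) - pre.values.astype(np.float32),
                    post.spacing_mm)


def _bbox(mask: np.ndarray) -> CropBox:
    idx = np.nonzero(mask)
    return tuple((int(i.min()), int(i.max()) + 1) for i in idx)  # type: ignore[return-value]


def _dilate_clip(box: CropBox, margin, shape) -> CropBox:
    return tuple(  # type: ignore[return-value]
        (max(0, a - m), min(n, b + m))
        for (a, b), m, n in zip(box, margin, shape))


def crop_to_box(v: Volume3D, box: CropBox) -> Volume3D:
    sl = tuple(slice(a, b) for a, b in box)
    return Volume3D(np.ascontiguousarray(v.values[sl]), v.spacing_mm)


def paste_into(grid: np.ndarray, patch: np.ndarray, box: CropBox) -> None:
    sl = tuple(slice(a, b) for a, b in box)
    grid[sl] = patch


def split_sides(breast_mask: MaskVolume, channels: list[Volume3D],
                margin_voxels=DEFAULT_MARGIN
                ) -> tuple[CroppedSide | None, CroppedSide | None]:
    """Split a bilateral volume at the column midline into per-breast crops.

    Returns ``(right_side, left_side)`` — low-column half first. Each crop box
    is the per-side breast bounding box dilated by ``margin_voxels`` and
    clipped to the grid. An empty side yields ``None`` with a warning.
    """
    lab = breast_mask.labels
    for ch in channels:
        if ch.shape != breast_mask.shape:
            raise ValueError("channel shape does not match breast mask")
    mid = lab.shape[1] // 2
    out: list[CroppedSide | None] = []
    for side, sl in (("right", slice(0, mid)), ("left", slice(mid, lab.shape[1]))):
        half = np.zeros_like(lab)
        half[:, sl, :] = lab[:, sl, :]
        if not half.any():
            warnings.warn(f"breast mask empty on the {side} side; returning "
                          "a single-side result", stacklevel=2)
            out.append(None)
            continue
        box = _dilate_clip(_bbox(half), margin_voxels, lab.shape)
        out.append(CroppedSide(channels=[crop_to_box(c, box) for c in channels],
                               side=side, crop_box=box))
    return out[0], out[1]


def stack_channels(side: CroppedSide) -> np.ndarray:
    """Stack the side's channels into a (C, rows, cols, slices) array.

    Channel order is whatever order the caller put into the CroppedSide; the
    pipeline convention is (pre-contrast T1, subtraction[, T2])."""
    return np.stack([c.values.astype(np.float32) for c in side.channels], axis=0)


def unstack_channels(stacked: np.ndarray, spacing_mm) -> list[Volume3D]:
    if stacked.ndim != 4:
        raise ValueError("expected a (C, rows, cols, slices) array")
    return [Volume3D(stacked[i].copy(), spacing_mm) for i in range(stacked.shape[0])]


def crop_box_to_json(box: CropBox) -> str:
    return json.dumps({"axes": [list(ab) for ab in box], "convention": "0-based half-open"})


def crop_box_from_json(text: str) -> CropBox:
    obj = json.loads(text)
    return tuple((int(a), int(b)) for a, b in obj["axes"])  # type: ignore[return-value]
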