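"""3-D volume containers and NIfTI I/O.

Axis convention used throughout the package (documented once, here):

* axis 0 — rows, anterior → posterior (the pectoral plane is a fixed row),
* axis 1 — columns, patient-right → patient-left (lateral),
* axis 2 — slices, inferior → superior (the anisotropic axis; slice spacing
  is typically 2–4× the in-plane spacing).

Network tensors use the same order as (C, rows, cols, slices), so stride and
kernel tuples are written depth-last, e.g. the in-plane-only downsampling step
is ``(2, 2, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "MaskVolume", "read_volume", "write_volume",
           "read_mask", "write_mask"]

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be 3 positive finite values, got {spacing}")
    return spacing


@dataclass
class Volume3D:
    """A scalar 3-D image with physical voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: Spacing

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume3D requires a 3-D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume3D values must be finite")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def astype(self, dtype) -> "Volume3D":
        return Volume3D(self.values.astype(dtype), self.spacing_mm)


@dataclass
class MaskVolume:
    """A binary 3-D label grid (0 = background, 1 = structure)."""

    labels: np.ndarray
    spacing_mm: Spacing

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"MaskVolume requires a 3-D array, got ndim={self.labels.ndim}")
        uniq = np.unique(self.labels)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"MaskVolume labels must be in {{0,1}}, got {uniq}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def count(self) -> int:
        return int(self.labels.sum())


def _affine(spacing: Spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(v: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(v.values), _affine(v.spacing_mm))
    img.header.set_zooms(v.spacing_mm)
    nib.save(img, str(path))


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: header has non-positive voxel spacing {zooms}")
    return Volume3D(np.asarray(data), tuple(float(z) for z in zooms))


def write_mask(m: MaskVolume, path) -> None:
    img = nib.Nifti1Image(m.labels.astype(np.uint8), _affine(m.spacing_mm))
    img.header.set_zooms(m.spacing_mm)
    nib.save(img, str(path))


def read_mask(path) -> MaskVolume:
    v = read_volume(path)
    return MaskVolume(np.rint(v.values).astype(np.uint8), v.spacing_mm)
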