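"""Synthetic multi-sequence breast MRI phantoms with known ground truth.

Every downstream stage of the package (cropping, training, inference,
quantification) is exercised on these phantoms, so the generator is
first-class, deterministic code: a given :class:`PhantomConfig` (including its
seed) always produces the bit-identical :class:`PhantomCase`.

The anatomy is deliberately schematic rather than physical. Two
half-ellipsoidal breasts sit anterior to a flat pectoral plane (a fixed row
index); fibroglandular tissue (FGT) is grown by biased random walks from
retroareolar seed points, smoothed, and thresholded by bisection so that the
realized FGT fraction of the breast volume hits the requested density.
Signal intensities are piecewise-constant per tissue class; the post-contrast
T1 volume equals the pre-contrast volume with FGT voxels multiplied by the
enhancement factor, before any corruption. Optional confounders: a spherical
enhancing lesion and a homogeneous high-signal implant hemisphere resting on
the pectoral plane (inside the breast mask, excluded from the FGT mask).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import MaskVolume, Volume3D, read_mask, read_volume, write_mask, write_volume

__all__ = [
    "PhantomConfig", "PhantomCase", "LesionSpec", "ImplantSpec",
    "DensityInfeasibleError", "generate_phantom", "corrupt_volume",
    "write_case", "read_case", "CASE_FILENAMES",
]

# tissue signal levels per sequence (arbitrary units)
_T1 = {"air": 0.05, "fat": 1.0, "fgt": 0.55, "muscle": 0.40,
       "lesion": 0.75, "implant": 1.30}
_T2 = {"air": 0.05, "fat": 0.65, "fgt": 0.90, "muscle": 0.45,
       "lesion": 0.95, "implant": 1.25}

CASE_FILENAMES = {
    "pre_t1": "pre_t1.nii.gz",
    "t2": "t2.nii.gz",
    "post_t1": "post_t1.nii.gz",
    "breast_mask": "breast_mask.nii.gz",
    "fgt_mask": "fgt_mask.nii.gz",
}


class DensityInfeasibleError(ValueError):
    """Requested FGT density cannot be realized for this breast geometry."""


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[int, int, int]  # voxel index
    radius_mm: float
    enhancement: float = 2.5


@dataclass(frozen=True)
class ImplantSpec:
    side: str  # "left" | "right"
    radius_mm: float


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (128, 128, 32)
    spacing_mm: tuple[float, float, float] = (1.4, 1.4, 3.0)
    target_density: float = 0.18
    n_fgt_seeds: int = 3
    enhancement_factor: float = 1.5
    lesion: LesionSpec | None = None
    implant: ImplantSpec | None = None
    noise_sd: float = 0.0
    bias_field_amplitude: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape axes must be >= 16, got {self.grid_shape}")
        if not (0.01 <= self.target_density <= 0.9):
            raise ValueError(f"target_density must lie in [0.01, 0.9], got {self.target_density}")
        if self.n_fgt_seeds < 1:
            raise ValueError("n_fgt_seeds must be >= 1")
        if self.enhancement_factor < 1.0:
            raise ValueError("enhancement_factor must be >= 1")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sd and bias_field_amplitude must be >= 0")
        if self.implant is not None and self.implant.side not in ("left", "right"):
            raise ValueError("implant.side must be 'left' or 'right'")


@dataclass
class PhantomCase:
    pre_t1: Volume3D
    t2: Volume3D
    post_t1: Volume3D
    breast_mask: MaskVolume
    fgt_mask: MaskVolume
    config: PhantomConfig

    def __post_init__(self):
        shapes = {m.shape for m in (self.pre_t1, self.t2, self.post_t1,
                                    self.breast_mask, self.fgt_mask)}
        if len(shapes) != 1:
            raise ValueError(f"case members disagree on shape: {shapes}")

    @property
    def realized_density(self) -> float:
        return self.fgt_mask.count() / max(self.breast_mask.count(), 1)


def _mm_grid(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _breast_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    """Sample the two half-ellipsoids and the pectoral row."""
    R, C, S = cfg.grid_shape
    sr, sc, ss = cfg.spacing_mm
    pect_row = int(round(0.70 * R))
    sides = []
    for frac in (0.27, 0.73):
        cc = (frac + rng.uniform(-0.015, 0.015)) * C * sc
        cs = (0.5 + rng.uniform(-0.04, 0.04)) * S * ss
        a = pect_row * sr * rng.uniform(0.80, 0.92)      # anterior extent
        b = 0.225 * C * sc * rng.uniform(0.85, 1.0)      # lateral semi-axis
        d = 0.42 * S * ss * rng.uniform(0.85, 1.0)       # slice-axis semi-axis
        sides.append({"center_col_mm": cc, "center_slice_mm": cs,
                      "a_mm": a, "b_mm": b, "d_mm": d})
    return pect_row, sides


def _render_breast_mask(cfg: PhantomConfig, pect_row: int, sides) -> np.ndarray:
    rr, cc, ss_ = _mm_grid(cfg.grid_shape, cfg.spacing_mm)
    pect_mm = pect_row * cfg.spacing_mm[0]
    mask = np.zeros(cfg.grid_shape, dtype=bool)
    for g in sides:
        e = (((rr - pect_mm) / g["a_mm"]) ** 2
             + ((cc - g["center_col_mm"]) / g["b_mm"]) ** 2
             + ((ss_ - g["center_slice_mm"]) / g["d_mm"]) ** 2)
        mask |= (e <= 1.0) & (rr <= pect_mm)
    return mask


def _grow_fgt_field(cfg: PhantomConfig, breast: np.ndarray, pect_row: int,
                    sides, rng: np.random.Generator) -> np.ndarray:
    """Biased random-walk growth from retroareolar seeds, then smoothing.

    The returned float field is positive everywhere inside the breast (a tiny
    smooth background is added) so that any density in (0, 1) is reachable by
    thresholding; the walk pattern dominates at ordinary densities.
    """
    R, C, S = cfg.grid_shape
    visits = np.zeros(cfg.grid_shape, dtype=np.float32)
    # steps biased posteriorly: FGT fans out from behind the nipple to the wall
    moves = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                      [0, 0, 1], [0, 0, -1]])
    probs = np.array([0.30, 0.10, 0.15, 0.15, 0.15, 0.15])
    breast_count = int(breast.sum())
    steps = max(150, int(0.25 * breast_count / max(cfg.n_fgt_seeds, 1)))
    for g in sides:
        col0 = int(round(g["center_col_mm"] / cfg.spacing_mm[1]))
        sl0 = int(round(g["center_slice_mm"] / cfg.spacing_mm[2]))
        tip = pect_row - int(round(g["a_mm"] / cfg.spacing_mm[0]))
        row0 = min(pect_row - 1, max(0, tip + max(2, (pect_row - tip) // 5)))
        for _ in range(cfg.n_fgt_seeds):
            pos = np.array([row0, col0 + rng.integers(-2, 3), sl0 + rng.integers(-2, 3)])
            pos = np.clip(pos, 0, np.array([R, C, S]) - 1)
            for _ in range(steps):
                visits[tuple(pos)] += 1.0
                step = moves[rng.choice(6, p=probs)]
                cand = pos + step
                if np.all(cand >= 0) and np.all(cand < (R, C, S)) and breast[tuple(cand)]:
                    pos = cand
    sigma_vox = np.maximum(2.2 / np.asarray(cfg.spacing_mm), 0.6)
    fld = gaussian_filter(visits, sigma=sigma_vox)
    background = gaussian_filter(rng.random(cfg.grid_shape).astype(np.float32),
                                 sigma=sigma_vox)
    peak = fld.max() if fld.max() > 0 else 1.0
    return fld / peak + 1e-3 * background


def _threshold_for_density(field: np.ndarray, region: np.ndarray,
                           target_count: int) -> np.ndarray:
    """Bisection on the threshold so that ~target_count region voxels survive."""
    vals = field[region]
    lo, hi = float(vals.min()) - 1e-6, float(vals.max()) + 1e-6
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        if int((vals > mid).sum()) > target_count:
            lo = mid
        else:
            hi = mid
    # pick the tighter of the two bracket ends
    n_lo, n_hi = int((vals > lo).sum()), int((vals > hi).sum())
    t = lo if abs(n_lo - target_count) <= abs(n_hi - target_count) else hi
    return region & (field > t)


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate one synthetic case; pure function of the config (seed included)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, C, S = config.grid_shape
    pect_row, sides = _breast_geometry(config, rng)
    breast = _render_breast_mask(config, pect_row, sides)
    if not breast.any():
        raise DensityInfeasibleError("breast geometry rendered empty")

    rr, cc, ss_ = _mm_grid(config.grid_shape, config.spacing_mm)

    lesion_vox = np.zeros(config.grid_shape, dtype=bool)
    if config.lesion is not None:
        c = config.lesion.center
        cmm = np.array([c[0] * config.spacing_mm[0], c[1] * config.spacing_mm[1],
                        c[2] * config.spacing_mm[2]])
        dist2 = (rr - cmm[0]) ** 2 + (cc - cmm[1]) ** 2 + (ss_ - cmm[2]) ** 2
        lesion_vox = (dist2 <= config.lesion.radius_mm ** 2) & breast

    implant_vox = np.zeros(config.grid_shape, dtype=bool)
    if config.implant is not None:
        g = sides[0] if config.implant.side == "right" else sides[1]
        cmm = np.array([pect_row * config.spacing_mm[0], g["center_col_mm"],
                        g["center_slice_mm"]])
        dist2 = (rr - cmm[0]) ** 2 + (cc - cmm[1]) ** 2 + (ss_ - cmm[2]) ** 2
        implant_vox = (dist2 <= config.implant.radius_mm ** 2) & (rr <= cmm[0])
        breast = breast | implant_vox  # implant counts as breast volume

    breast_count = int(breast.sum())
    candidate = breast & ~implant_vox & ~lesion_vox
    target_count = int(round(config.target_density * breast_count))
    if target_count > int(candidate.sum()):
        raise DensityInfeasibleError(
            f"target density {config.target_density:.3f} needs {target_count} voxels "
            f"but only {int(candidate.sum())} breast voxels are available for FGT")

    field_ = _grow_fgt_field(config, breast, pect_row, sides, rng)
    fgt = _threshold_for_density(field_, candidate, target_count)
    realized = fgt.sum() / breast_count
    if target_count > 0 and abs(realized - config.target_density) > 0.2 * config.target_density:
        raise DensityInfeasibleError(
            f"realized density {realized:.4f} outside +-20% of target "
            f"{config.target_density:.4f}")

    # paint tissue classes (priority: implant > lesion > fgt > fat > muscle > air)
    muscle = np.zeros(config.grid_shape, dtype=bool)
    muscle[pect_row:min(R, pect_row + max(2, int(0.12 * R)))] = True
    muscle &= ~breast

    def paint(levels):
        img = np.full(config.grid_shape, levels["air"], dtype=np.float32)
        img[muscle] = levels["muscle"]
        img[breast] = levels["fat"]
        img[fgt] = levels["fgt"]
        img[lesion_vox] = levels["lesion"]
        img[implant_vox] = levels["implant"]
        return img

    pre = paint(_T1)
    t2 = paint(_T2)
    post = pre.copy()
    post[fgt] *= config.enhancement_factor
    if config.lesion is not None:
        post[lesion_vox] *= config.lesion.enhancement

    corrupt_seeds = np.random.SeedSequence(config.seed).generate_state(4)
    mk = lambda arr, s: corrupt_volume(  # noqa: E731
        Volume3D(arr, config.spacing_mm), config.noise_sd,
        config.bias_field_amplitude, int(s) % (2 ** 31))
    return PhantomCase(
        pre_t1=mk(pre, corrupt_seeds[0]),
        t2=mk(t2, corrupt_seeds[1]),
        post_t1=mk(post, corrupt_seeds[2]),
        breast_mask=MaskVolume(breast.astype(np.uint8), config.spacing_mm),
        fgt_mask=MaskVolume(fgt.astype(np.uint8), config.spacing_mm),
        config=config,
    )


def _cosine_bias_field(shape, rng: np.random.Generator, max_mode: int = 2) -> np.ndarray:
    """Smooth zero-ish-mean field from low-order separable cosine modes,
    normalized to unit max amplitude."""
    field_ = np.zeros(shape, dtype=np.float64)
    axes = [np.cos(np.pi * k[:, None] * (np.arange(n) + 0.5) / n)
            for n, k in ((shape[i], np.arange(max_mode + 1)) for i in range(3))]
    for i in range(max_mode + 1):
        for j in range(max_mode + 1):
            for k in range(max_mode + 1):
                if i == j == k == 0:
                    continue
                c = rng.normal()
                field_ += c * (axes[0][i][:, None, None]
                               * axes[1][j][None, :, None]
                               * axes[2][k][None, None, :])
    amax = np.abs(field_).max()
    return (field_ / amax if amax > 0 else field_).astype(np.float32)


def corrupt_volume(v: Volume3D, noise_sd: float, bias_field_amplitude: float,
                   seed: int) -> Volume3D:
    """Apply a multiplicative low-frequency bias field and additive Gaussian
    noise: out = v * (1 + amplitude * g) + noise, E[out] = v * bias."""
    if noise_sd < 0 or bias_field_amplitude < 0:
        raise ValueError("noise_sd and bias_field_amplitude must be >= 0")
    if noise_sd == 0 and bias_field_amplitude == 0:
        return Volume3D(v.values.copy(), v.spacing_mm)
    rng = np.random.default_rng(seed)
    out = v.values.astype(np.float32)
    if bias_field_amplitude > 0:
        g = _cosine_bias_field(v.shape, rng)
        out = out * (1.0 + bias_field_amplitude * g)
    else:
        _ = rng  # keep the stream layout stable regardless of amplitude
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, v.shape).astype(np.float32)
    return Volume3D(out, v.spacing_mm)


def write_case(case: PhantomCase, directory, overwrite: bool = False) -> list[Path]:
    """Write the five NIfTI members plus a JSON sidecar with the config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / fn for k, fn in CASE_FILENAMES.items()}
    sidecar = directory / "config.json"
    existing = [p for p in list(paths.values()) + [sidecar] if p.exists()]
    if existing and not overwrite:
        raise FileExistsError(f"refusing to overwrite {existing[0]} (pass overwrite=True)")
    write_volume(case.pre_t1, paths["pre_t1"])
    write_volume(case.t2, paths["t2"])
    write_volume(case.post_t1, paths["post_t1"])
    write_mask(case.breast_mask, paths["breast_mask"])
    write_mask(case.fgt_mask, paths["fgt_mask"])
    cfg = dataclasses.asdict(case.config)
    sidecar.write_text(json.dumps(cfg, indent=2, default=list))
    return list(paths.values()) + [sidecar]


def read_case(directory) -> PhantomCase:
    directory = Path(directory)
    cfg_raw = json.loads((directory / "config.json").read_text())
    for key in ("grid_shape", "spacing_mm"):
        cfg_raw[key] = tuple(cfg_raw[key])
    if cfg_raw.get("lesion"):
        cfg_raw["lesion"] = LesionSpec(tuple(cfg_raw["lesion"]["center"]),
                                       cfg_raw["lesion"]["radius_mm"],
                                       cfg_raw["lesion"]["enhancement"])
    if cfg_raw.get("implant"):
        cfg_raw["implant"] = ImplantSpec(cfg_raw["implant"]["side"],
                                         cfg_raw["implant"]["radius_mm"])
    config = PhantomConfig(**cfg_raw)
    return PhantomCase(
        pre_t1=read_volume(directory / CASE_FILENAMES["pre_t1"]),
        t2=read_volume(directory / CASE_FILENAMES["t2"]),
        post_t1=read_volume(directory / CASE_FILENAMES["post_t1"]),
        breast_mask=read_mask(directory / CASE_FILENAMES["breast_mask"]),
        fgt_mask=read_mask(directory / CASE_FILENAMES["fgt_mask"]),
        config=config,
    )
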