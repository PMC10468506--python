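"""Segmentation evaluation, clinical quantification and statistics.

Segmentation quality is measured by the Dice similarity coefficient
DSC = 2|A∩B|/(|A|+|B|) and the average symmetric surface distance (ASSD) in
mm. Surfaces are defined as foreground voxels with at least one background
6-neighbour (the grid boundary counts as background) and distances are
Euclidean distances between border-voxel centers weighted by the physical
voxel spacing; ASSD pools the directed nearest-surface distances of both
masks and averages them.

Clinical quantities: FGT volume (mm³), breast density (FGT volume as a
percentage of breast volume) and background parenchymal enhancement (BPE),
defined as the percentage change of the mean FGT signal between the post- and
pre-contrast images. An alternative BPE reading — the fraction of FGT voxels
whose signal rises by more than a threshold — is available behind a flag.

The statistics layer provides Pearson correlation, case-level percentile
bootstrap confidence intervals, and paired two-sided sign-flip permutation
tests (exhaustive when the number of pairs allows, Monte Carlo otherwise;
the observed permutation is always included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion, distance_transform_edt

from .volume import MaskVolume, Volume3D

__all__ = [
    "CaseMetrics", "dice", "assd", "surface_voxels", "volume_mm3",
    "breast_density", "bpe", "pearson", "bootstrap_ci",
    "paired_permutation_test", "density_stratified_report",
]


@dataclass
class CaseMetrics:
    case_id: str
    dice: float
    assd_mm: float          # NaN when undefined (an empty mask)
    fgt_volume_mm3: float
    breast_volume_mm3: float
    density_pct: float
    bpe_pct: float


def _check_aligned(a: MaskVolume, b: MaskVolume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(a: MaskVolume, b: MaskVolume) -> float:
    """Dice similarity coefficient; both-empty is defined as 1.0."""
    _check_aligned(a, b)
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.labels, b.labels).sum())
    return 2.0 * inter / (na + nb)


_STRUCT6 = np.zeros((3, 3, 3), dtype=bool)
_STRUCT6[1, 1, 1] = _STRUCT6[0, 1, 1] = _STRUCT6[2, 1, 1] = True
_STRUCT6[1, 0, 1] = _STRUCT6[1, 2, 1] = _STRUCT6[1, 1, 0] = _STRUCT6[1, 1, 2] = True


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Border voxels: foreground with a background 6-neighbour (the grid edge
    counts as background)."""
    fg = mask.astype(bool)
    interior = binary_erosion(fg, structure=_STRUCT6, border_value=0)
    return fg & ~interior


def assd(a: MaskVolume, b: MaskVolume, spacing_mm=None) -> float:
    """Average symmetric surface distance in mm (pooled over both directions).

    Raises on an empty mask — the distance is undefined; aggregate callers
    should catch this and exclude the case with a warning."""
    _check_aligned(a, b)
    spacing = spacing_mm if spacing_mm is not None else a.spacing_mm
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    if a.count() == 0 or b.count() == 0:
        raise ValueError("ASSD undefined for an empty mask")
    sa = surface_voxels(a.labels)
    sb = surface_voxels(b.labels)
    # exact Euclidean distance to the nearest surface voxel of the other mask
    d_to_b = distance_transform_edt(~sb, sampling=spacing)
    d_to_a = distance_transform_edt(~sa, sampling=spacing)
    dists = np.concatenate([d_to_b[sa], d_to_a[sb]])
    return float(dists.mean())


def volume_mm3(mask: MaskVolume, spacing_mm=None) -> float:
    spacing = spacing_mm if spacing_mm is not None else mask.spacing_mm
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    return float(mask.count() * np.prod(spacing))


def breast_density(fgt: MaskVolume, breast: MaskVolume, spacing_mm=None) -> float:
    """Breast density: FGT volume as a percentage of breast volume."""
    _check_aligned(fgt, breast)
    if breast.count() == 0:
        raise ValueError("breast mask is empty; density undefined")
    if np.any(fgt.labels & ~breast.labels):
        warnings.warn("FGT mask extends outside the breast mask", stacklevel=2)
    return 100.0 * volume_mm3(fgt, spacing_mm) / volume_mm3(breast, spacing_mm)


def bpe(pre: Volume3D, post: Volume3D, fgt: MaskVolume,
        mode: str = "mean_signal", enhanced_threshold: float = 0.1) -> float:
    """Background parenchymal enhancement of the FGT, in percent.

    mode='mean_signal' (default): 100 * (mean_post - mean_pre) / mean_pre over
    FGT voxels. mode='enhanced_fraction': percentage of FGT voxels whose
    relative signal increase exceeds `enhanced_threshold`."""
    if pre.shape != post.shape or pre.shape != fgt.shape:
        raise ValueError("pre, post and FGT mask must be aligned")
    sel = fgt.labels.astype(bool)
    if not sel.any():
        raise ValueError("FGT mask is empty; BPE undefined")
    pre_vals = pre.values[sel].astype(np.float64)
    post_vals = post.values[sel].astype(np.float64)
    if mode == "mean_signal":
        mp = pre_vals.mean()
        if mp <= 0:
            raise ValueError("mean pre-contrast FGT signal must be positive")
        return float(100.0 * (post_vals.mean() - mp) / mp)
    if mode == "enhanced_fraction":
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = (post_vals - pre_vals) / np.where(pre_vals > 0, pre_vals, np.nan)
        return float(100.0 * np.nanmean(rel > enhanced_threshold))
    raise ValueError(f"unknown BPE mode {mode!r}")


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs two equal-length lists, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bootstrap_ci(values, statistic=np.mean, n_boot: int = 2000,
                 alpha: float = 0.05, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval from case-level resamples."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("bootstrap needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    if statistic is np.mean:  # vectorized fast path for the common case
        boots = values[idx].mean(axis=1)
    else:
        boots = np.array([statistic(values[row]) for row in idx])
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def paired_permutation_test(a_values, b_values, n_perm: int = 10000,
                            seed: int = 0) -> float:
    """Two-sided paired sign-flip permutation test; statistic = mean difference.

    Exhaustive over all 2^n sign patterns when that is no more than n_perm,
    otherwise Monte Carlo with the observed permutation included. All
    differences zero gives p = 1."""
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D arrays")
    d = a - b
    n = len(d)
    if np.all(d == 0):
        return 1.0
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, obs)
    if n <= 30 and 2 ** n <= n_perm:
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1) * 2 - 1
        perm = np.abs((signs * d[None, :]).mean(axis=1))
        return float((perm >= obs - tol).sum() / 2 ** n)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm = np.abs((signs * d[None, :]).mean(axis=1))
    return float((1 + (perm >= obs - tol).sum()) / (n_perm + 1))


def density_stratified_report(metrics: list[CaseMetrics], bins) -> pd.DataFrame:
    """Per-density-bin mean ± SD of Dice and ASSD.

    `bins` are density-percent bin edges (half-open [lo, hi), last bin
    closed). Empty bins are kept in the table with NaN statistics and a
    warning rather than silently dropped."""
    if not metrics:
        raise ValueError("no case metrics supplied")
    edges = np.asarray(bins, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    df = pd.DataFrame([vars(m) for m in metrics])
    which = np.digitize(df["density_pct"], edges[1:-1], right=False)
    rows = []
    for i in range(len(edges) - 1):
        sel = df[which == i]
        if sel.empty:
            warnings.warn(f"density bin [{edges[i]}, {edges[i + 1]}) is empty",
                          stacklevel=2)
        rows.append({
            "bin_lo_pct": edges[i], "bin_hi_pct": edges[i + 1], "n": len(sel),
            "dice_mean": sel["dice"].mean(), "dice_sd": sel["dice"].std(),
            "assd_mean_mm": sel["assd_mm"].mean(),
            "assd_sd_mm": sel["assd_mm"].std(),
        })
    return pd.DataFrame(rows)
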