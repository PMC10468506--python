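"""Segmentation networks.

Two architectures, both 3-D, both anisotropy-aware and both emitting deep-
supervision outputs:

* :class:`AnisoSwinUNet` — a shifted-window (Swin) transformer encoder with a
  convolutional decoder, in the SwinUNETR family. The distinguishing feature
  is anisotropic downsampling: the first ``aniso_stages`` resolution steps use
  in-plane-only 2x2 patch merging (stride ``(2,2,1)`` in row/col/slice order)
  and in-plane 3x3 kernels (``(3,3,1)``), so the coarse slice axis is left
  untouched until the in-plane resolution has caught up.
* :class:`BaselineUNet3D` — a plain conv U-Net with the max-pooling scheme
  ``(2,2,1), (2,2,1), (2,2,2), (2,2,2)`` and matching anisotropic kernels in
  the two top levels.

Default embedding widths for the transformer are (24, 48, 96, 192) with
(2, 4, 8, 16) attention heads across the four stages. ``tiny_*`` presets
shrink widths and windows for CPU-scale runs.

Inputs are ``(N, C, rows, cols, slices)`` arrays; spatial sizes that do not
divide the cumulative stride are symmetrically zero-padded and the main
logits are cropped back, so arbitrary crop boxes pass through. Deep-
supervision (auxiliary) logits are reported on the padded grid together with
their downsampling factors and the padding applied; the multi-scale loss
reuses that information.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .nn import Tensor

__all__ = [
    "AnisoSwinConfig", "BaselineUNetConfig", "NetworkOutput",
    "AnisoSwinUNet", "BaselineUNet3D",
    "build_swin_unet", "build_baseline_unet", "count_parameters",
    "tiny_swin_config", "tiny_unet_config",
    "config_to_yaml", "config_from_yaml", "save_checkpoint", "load_checkpoint",
]


# --------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class AnisoSwinConfig:
    embed_dims: tuple[int, ...] = (24, 48, 96, 192)
    heads: tuple[int, ...] = (2, 4, 8, 16)
    depths: tuple[int, ...] = (2, 2, 2, 2)
    aniso_stages: int = 2
    window: tuple[int, int, int] = (7, 7, 4)
    in_channels: int = 2
    n_classes: int = 2
    deep_supervision_levels: int = 2
    mlp_ratio: float = 4.0

    def validate(self) -> None:
        n = len(self.embed_dims)
        if not (len(self.heads) == len(self.depths) == n):
            raise ValueError("embed_dims, heads and depths must have equal length")
        if list(self.embed_dims) != sorted(self.embed_dims) or \
                len(set(self.embed_dims)) != n:
            raise ValueError("embed_dims must be strictly increasing")
        if self.aniso_stages > n:
            raise ValueError("aniso_stages cannot exceed the stage count")
        for d, h in zip(self.embed_dims, self.heads):
            if d % h:
                raise ValueError(f"embed dim {d} not divisible by head count {h}")
        if not (0 <= self.deep_supervision_levels <= n - 1):
            raise ValueError("deep_supervision_levels must be in [0, stages-1]")

    def stage_strides(self) -> list[tuple[int, int, int]]:
        """Per-resolution-step downsampling, (rows, cols, slices)."""
        return [(2, 2, 1) if i < self.aniso_stages else (2, 2, 2)
                for i in range(len(self.embed_dims))]

    def total_stride(self) -> tuple[int, int, int]:
        t = np.prod(np.array(self.stage_strides()), axis=0)
        return tuple(int(x) for x in t)


@dataclass(frozen=True)
class BaselineUNetConfig:
    channels: tuple[int, ...] = (32, 64, 128, 256, 320)
    pool_strides: tuple[tuple[int, int, int], ...] = (
        (2, 2, 1), (2, 2, 1), (2, 2, 2), (2, 2, 2))
    in_channels: int = 2
    n_classes: int = 2
    deep_supervision_levels: int = 2

    def validate(self) -> None:
        if len(self.channels) != len(self.pool_strides) + 1:
            raise ValueError("need one more channel width than pooling layers")
        if not (0 <= self.deep_supervision_levels <= len(self.pool_strides) - 1):
            raise ValueError("deep_supervision_levels out of range")

    def level_kernels(self) -> list[tuple[int, int, int]]:
        """(3,3,1) while the slice axis is still at full resolution."""
        kernels = []
        cum_d = 1
        for i in range(len(self.channels)):
            kernels.append((3, 3, 1) if cum_d == 1 and i < len(self.pool_strides)
                           and self.pool_strides[min(i, len(self.pool_strides) - 1)][2] == 1
                           else (3, 3, 3))
            if i < len(self.pool_strides):
                cum_d *= self.pool_strides[i][2]
        return kernels

    def total_stride(self) -> tuple[int, int, int]:
        t = np.prod(np.array(self.pool_strides), axis=0)
        return tuple(int(x) for x in t)


def tiny_swin_config(in_channels: int = 2, n_classes: int = 2) -> AnisoSwinConfig:
    """CPU-scale preset: quarter-width embeddings and a small window."""
    return AnisoSwinConfig(embed_dims=(12, 24, 48, 96), heads=(2, 4, 8, 16),
                           depths=(2, 2, 2, 2), window=(4, 4, 2),
                           in_channels=in_channels, n_classes=n_classes)


def tiny_unet_config(in_channels: int = 2, n_classes: int = 2) -> BaselineUNetConfig:
    return BaselineUNetConfig(channels=(8, 16, 32, 64, 128),
                              in_channels=in_channels, n_classes=n_classes)


@dataclass
class NetworkOutput:
    """Main logits at input resolution plus deep-supervision logits.

    ``aux_logits[i]`` lives on the padded grid downsampled by
    ``aux_factors[i]``; ``pad`` records the symmetric zero padding (per spatial
    axis, (before, after)) that was applied before the encoder.
    """

    main_logits: Tensor
    aux_logits: list[Tensor]
    aux_factors: list[tuple[int, int, int]]
    pad: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


# --------------------------------------------------------------------------
# shared blocks


class ConvBlock(nn.Module):
    """(conv -> instance norm -> leaky ReLU) x 2, nnUNet-style."""

    def __init__(self, cin, cout, kernel, rng):
        self.c1 = nn.Conv3d(cin, cout, kernel, rng)
        self.n1 = nn.InstanceNorm3d(cout)
        self.c2 = nn.Conv3d(cout, cout, kernel, rng)
        self.n2 = nn.InstanceNorm3d(cout)

    def forward(self, x):
        x = self.n1(self.c1(x)).leaky_relu(0.01)
        return self.n2(self.c2(x)).leaky_relu(0.01)


class UpBlock(nn.Module):
    """Nearest-neighbour upsample, concat skip, then a ConvBlock."""

    def __init__(self, cin, cskip, cout, factors, kernel, rng):
        self.factors = factors
        self.block = ConvBlock(cin + cskip, cout, kernel, rng)

    def forward(self, x, skip):
        x = x.upsample_nearest(self.factors)
        return self.block(nn.concat([x, skip], axis=1))


class Head(nn.Module):
    """1x1x1 projection to class logits (used for main and auxiliary heads)."""

    def __init__(self, cin, n_classes, rng):
        self.conv = nn.Conv3d(cin, n_classes, (1, 1, 1), rng)

    def forward(self, x):
        return self.conv(x)


def _pad_to_multiple(x: np.ndarray, mult: tuple[int, int, int]):
    pads = []
    for ax, m in enumerate(mult):
        n = x.shape[2 + ax]
        rem = (-n) % m
        pads.append((rem // 2, rem - rem // 2))
    if any(p != (0, 0) for p in pads):
        x = np.pad(x, ((0, 0), (0, 0)) + tuple(pads))
    return x, tuple(pads)


# --------------------------------------------------------------------------
# Swin components (token layout: (N, H, W, D, C))


def _window_segments(length: int, w: int, s: int):
    if s == 0 or length <= w:
        return [slice(0, length)]
    return [slice(0, length - w), slice(length - w, length - s),
            slice(length - s, length)]


def _shift_attn_mask(dims, window, shift) -> np.ndarray | None:
    """Standard Swin region mask for cyclic-shifted windows: -inf between
    tokens that wrapped around from different image regions."""
    if all(s == 0 for s in shift):
        return None
    ids = np.zeros(dims, dtype=np.int32)
    cnt = 0
    for sh in _window_segments(dims[0], window[0], shift[0]):
        for sw in _window_segments(dims[1], window[1], shift[1]):
            for sd in _window_segments(dims[2], window[2], shift[2]):
                ids[sh, sw, sd] = cnt
                cnt += 1
    nh, nw_, nd = (dims[i] // window[i] for i in range(3))
    wins = ids.reshape(nh, window[0], nw_, window[1], nd, window[2])
    wins = wins.transpose(0, 2, 4, 1, 3, 5).reshape(nh * nw_ * nd, -1)
    mask = np.where(wins[:, :, None] != wins[:, None, :], -1e4, 0.0)
    return mask.astype(np.float32)  # (n_windows, T, T)


class WindowAttention(nn.Module):
    def __init__(self, dim, heads, rng):
        self.dim, self.heads = dim, heads
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)

    def forward(self, tokens: Tensor, mask: np.ndarray | None) -> Tensor:
        # tokens: (N, nw, T, C)
        N, nw, T, C = tokens.shape
        h, hd = self.heads, self.dim // self.heads

        def split_heads(t):
            return t.reshape(N, nw, T, h, hd).transpose((0, 1, 3, 2, 4))

        q = split_heads(self.q(tokens)) * (1.0 / math.sqrt(hd))
        k = split_heads(self.k(tokens))
        v = split_heads(self.v(tokens))
        logits = q @ k.transpose((0, 1, 2, 4, 3))  # (N, nw, h, T, T)
        if mask is not None:
            logits = logits + Tensor(mask[None, :, None, :, :])
        attn = logits.softmax(axis=-1)
        out = (attn @ v).transpose((0, 1, 3, 2, 4)).reshape(N, nw, T, C)
        return self.proj(out)


class SwinBlock(nn.Module):
    def __init__(self, dim, heads, window, shifted, mlp_ratio, rng):
        self.window = window
        self.shifted = shifted
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, t: Tensor) -> Tensor:
        t = t + self._attention(self.norm1(t))
        return t + self.fc2(self.fc1(self.norm2(t)).gelu())

    def _attention(self, t: Tensor) -> Tensor:
        N, H, W, D, C = t.shape
        win = tuple(min(w, s) for w, s in zip(self.window, (H, W, D)))
        shift = tuple(w // 2 if (self.shifted and dim > w) else 0
                      for w, dim in zip(win, (H, W, D)))
        pads = tuple((0, (-s) % w) for s, w in zip((H, W, D), win))
        if any(p[1] for p in pads):
            t = t.pad(((0, 0),) + pads + ((0, 0),))
        Hp, Wp, Dp = t.shape[1:4]
        if any(shift):
            t = t.roll(tuple(-s for s in shift), axis=(1, 2, 3))
        mask = _shift_attn_mask((Hp, Wp, Dp), win, shift)
        nh, nw_, nd = Hp // win[0], Wp // win[1], Dp // win[2]
        t = t.reshape(N, nh, win[0], nw_, win[1], nd, win[2], C)
        t = t.transpose((0, 1, 3, 5, 2, 4, 6, 7))
        t = t.reshape(N, nh * nw_ * nd, win[0] * win[1] * win[2], C)
        t = self.attn(t, mask)
        t = t.reshape(N, nh, nw_, nd, win[0], win[1], win[2], C)
        t = t.transpose((0, 1, 4, 2, 5, 3, 6, 7)).reshape(N, Hp, Wp, Dp, C)
        if any(shift):
            t = t.roll(shift, axis=(1, 2, 3))
        if any(p[1] for p in pads):
            t = t[:, :H, :W, :D, :]
        return t


class PatchDown(nn.Module):
    """Space-to-depth by per-axis factors followed by a linear projection;
    serves as both patch embedding and patch merging."""

    def __init__(self, cin, cout, factors, rng):
        self.factors = factors
        self.norm = nn.LayerNorm(cin * int(np.prod(factors)))
        self.lin = nn.Linear(cin * int(np.prod(factors)), cout, rng)

    def forward(self, t: Tensor) -> Tensor:
        # t: (N, H, W, D, C), spatial dims divisible by factors
        N, H, W, D, C = t.shape
        fh, fw, fd = self.factors
        t = t.reshape(N, H // fh, fh, W // fw, fw, D // fd, fd, C)
        t = t.transpose((0, 1, 3, 5, 2, 4, 6, 7))
        t = t.reshape(N, H // fh, W // fw, D // fd, fh * fw * fd * C)
        return self.lin(self.norm(t))


def _to_tokens(x: Tensor) -> Tensor:
    return x.transpose((0, 2, 3, 4, 1))


def _to_conv(t: Tensor) -> Tensor:
    return t.transpose((0, 4, 1, 2, 3))


# --------------------------------------------------------------------------
# networks


class AnisoSwinUNet(nn.Module):
    """Shifted-window transformer encoder + convolutional decoder with deep
    supervision; slice-axis resolution is preserved through the anisotropic
    stages."""

    def __init__(self, config: AnisoSwinConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        dims = config.embed_dims
        strides = config.stage_strides()
        full_kernel = (3, 3, 1) if strides[0][2] == 1 else (3, 3, 3)

        self.enc_input = ConvBlock(config.in_channels, dims[0], full_kernel, rng)
        self.embed = PatchDown(config.in_channels, dims[0], strides[0], rng)
        self.stages = nn.ModuleList()
        self.merges = nn.ModuleList()
        for i, dim in enumerate(dims):
            blocks = nn.ModuleList([
                SwinBlock(dim, config.heads[i], config.window,
                          shifted=(b % 2 == 1), mlp_ratio=config.mlp_ratio, rng=rng)
                for b in range(config.depths[i])])
            self.stages.append(blocks)
            if i + 1 < len(dims):
                self.merges.append(PatchDown(dim, dims[i + 1], strides[i + 1], rng))

        self.skip_convs = nn.ModuleList([
            ConvBlock(dims[i], dims[i], self._stage_kernel(i), rng)
            for i in range(len(dims))])
        self.ups = nn.ModuleList([
            UpBlock(dims[i + 1], dims[i], dims[i], strides[i + 1],
                    self._stage_kernel(i), rng)
            for i in reversed(range(len(dims) - 1))])
        self.up0 = UpBlock(dims[0], dims[0], dims[0], strides[0], full_kernel, rng)
        self.head = Head(dims[0], config.n_classes, rng)
        self.aux_heads = nn.ModuleList([
            Head(dims[lvl], config.n_classes, rng)
            for lvl in range(config.deep_supervision_levels)])

    def _stage_kernel(self, level: int) -> tuple[int, int, int]:
        """Conv kernel at stage `level`'s resolution: in-plane (3,3,1) while
        the slice axis is still at full resolution."""
        cum_d = 1
        for s in self.config.stage_strides()[:level + 1]:
            cum_d *= s[2]
        return (3, 3, 1) if cum_d == 1 else (3, 3, 3)

    def forward(self, x) -> NetworkOutput:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        orig = x.shape[2:]
        xd, pads = _pad_to_multiple(x.data, self.config.total_stride())
        x = Tensor(xd, requires_grad=x.requires_grad) if xd is not x.data else x

        full = self.enc_input(x)
        t = self.embed(_to_tokens(x))
        feats = []
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                t = blk(t)
            feats.append(_to_conv(t))
            if i < len(self.merges):
                t = self.merges[i](t)

        skips = [self.skip_convs[i](feats[i]) for i in range(len(feats))]
        y = skips[-1]
        dec_feats = {}
        for j, up in enumerate(self.ups):
            lvl = len(self.stages) - 2 - j
            y = up(y, skips[lvl])
            dec_feats[lvl] = y
        y = self.up0(y, full)
        logits = self.head(y)

        strides = self.config.stage_strides()
        aux_logits, aux_factors = [], []
        cum = np.array(strides[0])
        for lvl in range(self.config.deep_supervision_levels):
            factor = cum.copy()
            for s in strides[1:lvl + 1]:
                factor *= np.array(s)
            aux_logits.append(self.aux_heads[lvl](dec_feats[lvl] if lvl in dec_feats
                                                  else skips[lvl]))
            aux_factors.append(tuple(int(f) for f in factor))

        sl = (slice(None), slice(None)) + tuple(
            slice(p0, p0 + n) for (p0, _), n in zip(pads, orig))
        return NetworkOutput(main_logits=logits[sl], aux_logits=aux_logits,
                             aux_factors=aux_factors, pad=pads)


class BaselineUNet3D(nn.Module):
    """Conv U-Net with the anisotropic pooling scheme
    (2,2,1), (2,2,1), (2,2,2), (2,2,2) (rows, cols, slices)."""

    def __init__(self, config: BaselineUNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        kernels = config.level_kernels()
        self.enc = nn.ModuleList()
        cin = config.in_channels
        for i, c in enumerate(ch):
            self.enc.append(ConvBlock(cin, c, kernels[i], rng))
            cin = c
        self.ups = nn.ModuleList([
            UpBlock(ch[i + 1], ch[i], ch[i], config.pool_strides[i], kernels[i], rng)
            for i in reversed(range(len(ch) - 1))])
        self.head = Head(ch[0], config.n_classes, rng)
        self.aux_heads = nn.ModuleList([
            Head(ch[lvl], config.n_classes, rng)
            for lvl in range(1, 1 + config.deep_supervision_levels)])

    def forward(self, x) -> NetworkOutput:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        orig = x.shape[2:]
        xd, pads = _pad_to_multiple(x.data, self.config.total_stride())
        x = Tensor(xd, requires_grad=x.requires_grad) if xd is not x.data else x

        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            if i < len(self.config.pool_strides):
                skips.append(x)
                x = x.maxpool3d(self.config.pool_strides[i])
        dec_feats = {}
        y = x
        for j, up in enumerate(self.ups):
            lvl = len(self.enc) - 2 - j
            y = up(y, skips[lvl])
            dec_feats[lvl] = y
        logits = self.head(y)

        aux_logits, aux_factors = [], []
        for lvl in range(1, 1 + self.config.deep_supervision_levels):
            factor = np.prod(np.array(self.config.pool_strides[:lvl]), axis=0)
            aux_logits.append(self.aux_heads[lvl - 1](dec_feats[lvl]))
            aux_factors.append(tuple(int(f) for f in factor))

        sl = (slice(None), slice(None)) + tuple(
            slice(p0, p0 + n) for (p0, _), n in zip(pads, orig))
        return NetworkOutput(main_logits=logits[sl], aux_logits=aux_logits,
                             aux_factors=aux_factors, pad=pads)


# --------------------------------------------------------------------------
# plumbing


def build_swin_unet(config: AnisoSwinConfig, seed: int = 0) -> AnisoSwinUNet:
    return AnisoSwinUNet(config, seed=seed)


def build_baseline_unet(config: BaselineUNetConfig, seed: int = 0) -> BaselineUNet3D:
    return BaselineUNet3D(config, seed=seed)


def count_parameters(network: nn.Module) -> int:
    return int(sum(p.data.size for p in network.parameters()))


_CONFIG_CLASSES = {"AnisoSwinConfig": AnisoSwinConfig,
                   "BaselineUNetConfig": BaselineUNetConfig}


def _cfg_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    d["__class__"] = type(config).__name__
    return d


def _cfg_from_dict(d: dict):
    d = dict(d)
    cls = _CONFIG_CLASSES[d.pop("__class__")]
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    return cls(**d)


def config_to_yaml(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_cfg_to_dict(config), fh)


def config_from_yaml(path):
    with open(path) as fh:
        return _cfg_from_dict(yaml.safe_load(fh))


def save_checkpoint(network: nn.Module, path) -> None:
    state = network.state_dict()
    meta = json.dumps(_cfg_to_dict(network.config))
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = _cfg_from_dict(meta)
    if isinstance(config, AnisoSwinConfig):
        net = AnisoSwinUNet(config)
    else:
        net = BaselineUNet3D(config)
    net.load_state_dict(state)
    return net
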