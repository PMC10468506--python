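"""Shared fixtures: small desk-scale phantoms and helper networks.

All fixtures are deterministic (fixed seeds) so the suite is reproducible.
The phantom grid used in tests is 64x64x16 at 2.8x2.8x6.0 mm — the same
~1:2 in-plane-to-slice anisotropy ratio as the default phantom, at a size a
single CPU handles comfortably.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import mammoseg as ms

GRID = (64, 64, 16)
SPACING = (2.8, 2.8, 6.0)


def make_phantom(density=0.18, seed=1, noise_sd=0.0, bias=0.0,
                 enhancement=1.5, grid=GRID, spacing=SPACING, **kw) -> ms.PhantomCase:
    cfg = ms.PhantomConfig(grid_shape=grid, spacing_mm=spacing,
                           target_density=density, noise_sd=noise_sd,
                           bias_field_amplitude=bias,
                           enhancement_factor=enhancement, seed=seed, **kw)
    return ms.generate_phantom(cfg)


@pytest.fixture(scope="session")
def phantom_case() -> ms.PhantomCase:
    """Noiseless reference phantom, 18% target density."""
    return make_phantom()


@pytest.fixture(scope="session")
def noisy_case() -> ms.PhantomCase:
    return make_phantom(seed=2, noise_sd=0.02, bias=0.2)


def micro_swin_config(**kw) -> ms.AnisoSwinConfig:
    """Very small transformer for structural/gradient tests."""
    return ms.AnisoSwinConfig(embed_dims=(4, 8, 16, 32), heads=(2, 2, 4, 4),
                              depths=(2, 1, 1, 1), window=(4, 4, 2),
                              deep_supervision_levels=2, mlp_ratio=2.0, **kw)


def micro_unet_config(**kw) -> ms.BaselineUNetConfig:
    return ms.BaselineUNetConfig(channels=(4, 8, 16, 32, 32), **kw)


class VoxelwiseNet:
    """A flip-equivariant stand-in network: logits are a pointwise function of
    the first input channel, so sliding-window / TTA algebra can be tested
    exactly."""

    def __init__(self, n_classes: int = 2, scale: float = 1.0):
        self.config = SimpleNamespace(n_classes=n_classes)
        self.scale = scale

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float32)
        ch0 = x[:, 0]
        logits = np.stack([-self.scale * ch0, self.scale * ch0], axis=1)
        return SimpleNamespace(main_logits=SimpleNamespace(data=logits))


class ConstantNet:
    """Predicts a fixed class everywhere (used for empty-prediction paths)."""

    def __init__(self, favored_class: int = 0, n_classes: int = 2):
        self.config = SimpleNamespace(n_classes=n_classes)
        self.favored = favored_class

    def __call__(self, x):
        x = np.asarray(x)
        logits = np.zeros((x.shape[0], self.config.n_classes) + x.shape[2:],
                          dtype=np.float32)
        logits[:, self.favored] = 5.0
        return SimpleNamespace(main_logits=SimpleNamespace(data=logits))


def overfit_train_config(max_steps: int = 200, lr: float = 2e-3,
                         patch=GRID) -> ms.TrainConfig:
    """Overfit-sanity recipe: no augmentation, higher learning rate, early
    exit once the training Dice target is reached."""
    return ms.TrainConfig(learning_rate=lr, patch_size=patch,
                          max_epochs=max_steps // 10, steps_per_epoch=10,
                          augment=None, seed=0, stop_at_train_dice=0.90,
                          early_stop_patience_epochs=10_000)


def single_case_fold(case_id: str) -> ms.FoldSplit:
    return ms.FoldSplit(k=1, folds=(ms.Fold(train=(case_id,), val=(case_id,),
                                            test=()),))
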