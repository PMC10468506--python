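"""Overfit the tiny anisotropic Swin transformer on one phantom.

A quick trainability check: on a single noiseless case the network should
reach a training Dice of 0.9 within a couple of hundred optimization steps.
Uses the overfit recipe (no augmentation, learning rate 2e-3); production
training uses lr 1e-4 with the full augmentation stack.
"""

import mammoseg as ms

case = ms.generate_phantom(ms.PhantomConfig(
    grid_shape=(64, 64, 16), spacing_mm=(2.8, 2.8, 6.0),
    target_density=0.18, seed=1))
samples = ms.cases_from_phantom(case, "demo")   # one sample per breast side
ids = tuple(s.case_id for s in samples)
folds = ms.FoldSplit(k=1, folds=(ms.Fold(train=ids, val=(ids[0],), test=()),))

net = ms.build_swin_unet(ms.tiny_swin_config(), seed=0)
print(f"parameters: {ms.count_parameters(net):,}")

config = ms.TrainConfig(learning_rate=2e-3, patch_size=(64, 64, 16),
                        max_epochs=20, steps_per_epoch=10, augment=None,
                        seed=0, stop_at_train_dice=0.90,
                        early_stop_patience_epochs=10_000)
result = ms.train_model(net, samples, folds, 0, config)
print(result.history.to_string(index=False,
                               float_format=lambda v: f"{v:.3f}"))
print(f"reached Dice {result.history.train_dice.iloc[-1]:.3f} "
      f"after {result.stopped_epoch * config.steps_per_epoch} steps")
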