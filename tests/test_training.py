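"""Folds, losses, augmentation, patch sampling and the early-stopping loop."""

import math

import numpy as np
import pytest

import mammoseg as ms
from mammoseg.models import NetworkOutput
from mammoseg.nn import Tensor

from conftest import micro_unet_config, overfit_train_config, single_case_fold


class TestFolds:
    def test_ten_cases_five_folds(self):
        ids = [f"c{i}" for i in range(10)]
        split = ms.make_folds(ids, k=5, seed=0)
        assert split.k == 5
        for f in split.folds:
            assert len(f.test) == 2
            # 8 non-test cases -> 80/20 means 6 train, 2 validation
            assert len(f.train) == 6 and len(f.val) == 2
            assert set(f.train) | set(f.val) | set(f.test) == set(ids)
            assert not (set(f.train) & set(f.val))
            assert not (set(f.train) & set(f.test))

    def test_test_folds_partition_cohort(self):
        ids = [f"c{i}" for i in range(13)]
        split = ms.make_folds(ids, k=5, seed=1)
        all_test = [c for f in split.folds for c in f.test]
        assert sorted(all_test) == sorted(ids)

    def test_deterministic_in_seed(self):
        ids = [f"c{i}" for i in range(12)]
        assert ms.make_folds(ids, 4, seed=7) == ms.make_folds(ids, 4, seed=7)
        assert ms.make_folds(ids, 4, seed=7) != ms.make_folds(ids, 4, seed=8)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            ms.make_folds(["a", "b"], k=1)


class TestDiceCELoss:
    def test_confident_correct_prediction_small_loss(self):
        rng = np.random.default_rng(0)
        target = (rng.random((1, 8, 8, 4)) > 0.5).astype(np.int64)
        logits = np.zeros((1, 2, 8, 8, 4), dtype=np.float32)
        logits[:, 1] = np.where(target == 1, 20.0, -20.0)
        logits[:, 0] = -logits[:, 1]
        loss = ms.dice_ce_loss(Tensor(logits), target)
        assert 0 <= float(loss.data) < 1e-3

    def test_uniform_logits_half_foreground_closed_form(self):
        """Uniform logits: CE = ln 2 per voxel; soft Dice with p=1/2 on a
        half-foreground target contributes 1/2."""
        target = np.zeros((1, 4, 4, 4), dtype=np.int64)
        target[:, :2] = 1
        logits = np.zeros((1, 2, 4, 4, 4), dtype=np.float32)
        loss = float(ms.dice_ce_loss(Tensor(logits), target).data)
        assert loss == pytest.approx(0.5 + math.log(2.0), abs=1e-4)

    def test_loss_decreases_under_optimization(self):
        net = ms.build_baseline_unet(micro_unet_config(), seed=0)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 2, 16, 16, 8)).astype(np.float32)
        target = (rng.random((1, 16, 16, 8)) > 0.7).astype(np.int64)
        from mammoseg.nn import AdamW
        opt = AdamW(net.parameters(), lr=1e-3)
        losses = []
        for _ in range(50):
            loss = ms.dice_ce_loss(net(x).main_logits, target)
            losses.append(float(loss.data))
            net.zero_grad()
            loss.backward()
            opt.step()
        assert losses[-1] < losses[0] * 0.8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ms.dice_ce_loss(Tensor(np.zeros((1, 2, 4, 4, 4))),
                            np.zeros((1, 4, 4, 5), dtype=np.int64))


class TestMultiscaleLoss:
    @staticmethod
    def _fake_output(rng, pads=((0, 0), (0, 0), (0, 0))):
        main = Tensor(rng.standard_normal((1, 2, 8, 8, 4)).astype(np.float32))
        aux = [Tensor(rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)),
               Tensor(rng.standard_normal((1, 2, 2, 2, 4)).astype(np.float32))]
        return NetworkOutput(main_logits=main, aux_logits=aux,
                             aux_factors=[(2, 2, 1), (4, 4, 1)], pad=pads)

    def test_main_only_weights_equal_plain_loss(self):
        rng = np.random.default_rng(0)
        out = self._fake_output(rng)
        target = (rng.random((1, 8, 8, 4)) > 0.5).astype(np.int64)
        a = float(ms.multiscale_loss(out, target, weights=(1, 0, 0)).data)
        b = float(ms.dice_ce_loss(out.main_logits, target).data)
        assert a == pytest.approx(b, rel=1e-6)

    def test_manual_weighted_sum_oracle(self):
        rng = np.random.default_rng(1)
        out = self._fake_output(rng)
        target = (rng.random((1, 8, 8, 4)) > 0.5).astype(np.int64)
        got = float(ms.multiscale_loss(out, target, weights=(1, 0.5, 0.25)).data)
        t1 = target[:, 1::2, 1::2, :]
        t2 = target[:, 2::4, 2::4, :]
        expect = (1.0 * float(ms.dice_ce_loss(out.main_logits, target).data)
                  + 0.5 * float(ms.dice_ce_loss(out.aux_logits[0], t1).data)
                  + 0.25 * float(ms.dice_ce_loss(out.aux_logits[1], t2).data)
                  ) / 1.75
        assert got == pytest.approx(expect, rel=1e-6)

    def test_weight_count_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        out = self._fake_output(rng)
        target = np.zeros((1, 8, 8, 4), dtype=np.int64)
        with pytest.raises(ValueError):
            ms.multiscale_loss(out, target, weights=(1, 0.5))


class TestAugment:
    @staticmethod
    def _sample(seed=0, shape=(12, 12, 8)):
        rng = np.random.default_rng(seed)
        ch = rng.standard_normal((2,) + shape).astype(np.float32)
        mk = (rng.random(shape) > 0.6).astype(np.uint8)
        return ch, mk

    def test_zero_probabilities_identity(self):
        ch, mk = self._sample()
        out_ch, out_mk = ms.augment(ch, mk, seed=5,
                                    config=ms.AugmentConfig.identity())
        assert np.array_equal(out_ch, ch)
        assert np.array_equal(out_mk, mk)

    def test_flip_is_involution(self):
        ch, mk = self._sample()
        cfg = ms.AugmentConfig.identity().__class__(
            p_flip=1.0, flip_axes=(1,), p_affine=0, p_ghosting=0, p_noise=0,
            p_blur=0, p_bias=0, p_gamma=0)
        once_ch, once_mk = ms.augment(ch, mk, seed=0, config=cfg)
        twice_ch, twice_mk = ms.augment(once_ch, once_mk, seed=0, config=cfg)
        assert np.array_equal(twice_ch, ch)
        assert np.array_equal(twice_mk, mk)

    def test_deterministic_per_seed(self):
        ch, mk = self._sample()
        a = ms.augment(ch, mk, seed=42)
        b = ms.augment(ch, mk, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mask_stays_binary_over_sampled_chains(self):
        ch, mk = self._sample(seed=3)
        for seed in range(100):
            _, out_mk = ms.augment(ch, mk, seed=seed)
            assert set(np.unique(out_mk)) <= {0, 1}

    def test_spatial_agreement_of_image_and_mask(self):
        """A mask-shaped structure in the image must move with the mask."""
        shape = (16, 16, 8)
        mk = np.zeros(shape, dtype=np.uint8)
        mk[4:8, 5:9, 2:5] = 1
        ch = np.stack([mk.astype(np.float32)])
        cfg = ms.AugmentConfig(p_flip=1.0, flip_axes=(0, 1, 2), p_affine=0,
                               p_ghosting=0, p_noise=0, p_blur=0, p_bias=0,
                               p_gamma=0)
        out_ch, out_mk = ms.augment(ch, mk, seed=9, config=cfg)
        assert np.array_equal(out_ch[0] > 0.5, out_mk.astype(bool))


class TestSamplePatch:
    def test_small_side_padded_to_whole(self):
        ch = np.ones((2, 5, 6, 4), dtype=np.float32)
        mk = np.ones((5, 6, 4), dtype=np.uint8)
        out_ch, out_mk = ms.sample_patch(ch, mk, (8, 8, 8),
                                         np.random.default_rng(0))
        assert out_ch.shape == (2, 8, 8, 8)
        assert out_mk.sum() == mk.sum()  # the whole (padded) side is returned

    def test_two_position_axis_uniformly_sampled(self):
        ch = np.zeros((1, 3, 2, 2), dtype=np.float32)
        ch[0, :, 0, 0] = [0.0, 1.0, 2.0]
        mk = np.zeros((3, 2, 2), dtype=np.uint8)
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(1000):
            out_ch, _ = ms.sample_patch(ch, mk, (2, 2, 2), rng)
            seen.add(float(out_ch[0, 0, 0, 0]))
        assert seen == {0.0, 1.0}

    def test_mask_cropped_identically(self):
        rng = np.random.default_rng(1)
        ch = rng.standard_normal((1, 10, 10, 6)).astype(np.float32)
        mk = (ch[0] > 0).astype(np.uint8)
        out_ch, out_mk = ms.sample_patch(ch, mk, (4, 4, 4), rng)
        assert np.array_equal(out_ch[0] > 0, out_mk.astype(bool))


class TestEarlyStopping:
    def test_reference_trace(self):
        """Losses (1.0, 0.9, 0.95, 0.97) with patience 2: best is epoch 2 and
        training stops right after epoch 4."""
        stopper = ms.EarlyStopper(patience=2)
        decisions = [stopper.update(e, v)
                     for e, v in enumerate((1.0, 0.9, 0.95, 0.97), start=1)]
        assert decisions == [False, False, False, True]
        assert stopper.best_epoch == 2

    def test_returns_argmin_epoch_on_random_traces(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            trace = rng.random(20)
            stopper = ms.EarlyStopper(patience=100)
            for e, v in enumerate(trace, start=1):
                stopper.update(e, float(v))
            assert stopper.best_epoch == int(np.argmin(trace)) + 1


class TestTrainLoop:
    @staticmethod
    def _toy_case(seed=0):
        rng = np.random.default_rng(seed)
        mk = (rng.random((16, 16, 8)) > 0.7).astype(np.uint8)
        ch = np.stack([mk + 0.1 * rng.standard_normal((16, 16, 8)),
                       rng.standard_normal((16, 16, 8))]).astype(np.float32)
        return ms.TrainingCase("toy", ch, mk)

    def test_same_seed_reproducible(self):
        results = []
        for _ in range(2):
            net = ms.build_baseline_unet(micro_unet_config(), seed=0)
            cfg = ms.TrainConfig(learning_rate=1e-3, patch_size=(16, 16, 8),
                                 max_epochs=2, steps_per_epoch=3, augment=None,
                                 seed=0, early_stop_patience_epochs=100)
            res = ms.train_model(net, [self._toy_case()], single_case_fold("toy"),
                                 0, cfg)
            results.append(res.history.val_loss.tolist())
        assert results[0] == results[1]

    def test_restores_best_validation_weights(self):
        net = ms.build_baseline_unet(micro_unet_config(), seed=0)
        cfg = ms.TrainConfig(learning_rate=1e-3, patch_size=(16, 16, 8),
                             max_epochs=4, steps_per_epoch=2, augment=None,
                             seed=0, early_stop_patience_epochs=100)
        case = self._toy_case()
        res = ms.train_model(net, [case], single_case_fold("toy"), 0, cfg)
        best = res.history.val_loss.min()
        # re-evaluate restored weights on the deterministic validation patch
        ch, mk = ms.sample_patch(case.channels, case.mask, (16, 16, 8),
                                 np.random.default_rng(0))
        from mammoseg.nn import no_grad
        with no_grad():
            val = float(ms.multiscale_loss(net(ch[None]),
                                           mk[None].astype(np.int64)).data)
        assert val == pytest.approx(best, rel=1e-5)
        assert res.best_epoch == int(res.history.val_loss.idxmin()) + 1
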