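"""Losses, augmentation pairing, freeze contracts, staged training."""
import math

import numpy as np
import pytest

from cgsnet.models import default_config
from cgsnet.patch_sampler import PatchPair, PatchRecord, PatchCategory
from cgsnet.training import (AugmentationConfig, LossConfig,
                             RegularizationConfig, SegDataset,
                             TrainingSchedule, augment_pair, composite_loss,
                             dataset_from_pairs, dice_loss, focal_loss,
                             penalty, retrain_combined, train_dual,
                             train_single, optimizer_groups)
from cgsnet.nn.tensor import Tensor
from cgsnet import nn


def scalar_oracle_composite(p, t, gamma=2.0, eps=1e-6):
    """Independent scalar-by-scalar evaluation of 0.95 focal + 0.05 dice."""
    focal = 0.0
    for pi, ti in zip(np.ravel(p), np.ravel(t)):
        pc = min(max(pi, eps), 1 - eps)
        pt = pc if ti == 1 else 1 - pc
        focal += -((1 - pt) ** gamma) * math.log(pt)
    focal /= np.size(p)
    inter = sum(pi * ti for pi, ti in zip(np.ravel(p), np.ravel(t)))
    dice = 1 - (2 * inter + eps) / (np.sum(p) + np.sum(t) + eps)
    return 0.95 * focal + 0.05 * dice


class TestLosses:
    def test_perfect_prediction_is_nearly_zero(self):
        t = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert composite_loss(t, t).item() <= 1e-6

    def test_matches_scalar_oracle(self):
        p = np.array([[0.9, 0.1], [0.8, 0.2]])
        t = np.array([[1.0, 0.0], [1.0, 0.0]])
        got = composite_loss(p, t).item()
        want = scalar_oracle_composite(p, t)
        assert abs(got - want) < 1e-10

    def test_component_weights_recovered_by_differentiation(self):
        # d composite / d focal = 0.95 and d composite / d dice = 0.05,
        # recovered by linearity on fixed inputs
        p = np.array([[0.7, 0.3]])
        t = np.array([[1.0, 0.0]])
        f = focal_loss(p, t).item()
        d = dice_loss(p, t).item()
        c = composite_loss(p, t).item()
        eps = 1e-6
        for w_f in (0.95,):
            assert abs(c - (w_f * f + (1 - w_f) * d)) < 1e-12
        cfg2 = LossConfig(focal_weight=0.5, dice_weight=0.5)
        assert abs(composite_loss(p, t, cfg2).item() - 0.5 * (f + d)) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_invalid_weighting_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(focal_weight=0.9, dice_weight=0.05)


class TestPenalty:
    def test_zero_when_nothing_eligible(self):
        assert penalty([], RegularizationConfig(l1=1.0, l2=1.0)).item() == 0.0

    def test_decoder_only_penalty_matches_hand_sum(self, rng):
        lin = nn.Linear(3, 3, rng=rng)
        reg = RegularizationConfig(l1=0.3, l2=0.7)
        got = penalty(lin.parameters(), reg).item()
        want = sum(0.3 * np.abs(p.data).sum() + 0.7 * (p.data ** 2).sum()
                   for p in lin.parameters())
        assert abs(got - want) < 1e-5

    def test_zero_coefficients_give_zero(self, rng):
        lin = nn.Linear(3, 3, rng=rng)
        assert penalty(lin.parameters(), RegularizationConfig()).item() == 0.0


def _toy_pair(rng):
    img = (rng.random((224, 224, 3)) * 255).astype(np.uint8)
    ctx = (rng.random((224, 224, 3)) * 255).astype(np.uint8)
    mask = (rng.random((224, 224)) < 0.3).astype(np.uint8)
    cmask = (rng.random((224, 224)) < 0.3).astype(np.uint8)
    rec = PatchRecord("s", PatchCategory.cancer, (112, 112), 1, 1.0, 0.3)
    return PatchPair(img, ctx, mask, cmask, rec)


class TestAugmentation:
    def test_identity_draw_leaves_pair_unchanged(self, rng):
        pair = _toy_pair(rng)
        cfg = AugmentationConfig(p_geometric=0.0, p_color=0.0)
        out = augment_pair(pair, cfg, np.random.default_rng(0))
        assert np.array_equal(out.detail_image, pair.detail_image)
        assert np.array_equal(out.detail_mask, pair.detail_mask)

    def test_flip_applies_identically_to_images_and_masks(self, rng):
        pair = _toy_pair(rng)
        cfg = AugmentationConfig(transpose=False, vertical_flip=False,
                                 rotate90=False, affine=False,
                                 horizontal_flip=True, p_geometric=1.0,
                                 p_color=0.0)
        out = augment_pair(pair, cfg, np.random.default_rng(1))
        assert np.array_equal(out.detail_mask, pair.detail_mask[:, ::-1])
        assert np.array_equal(out.detail_image, pair.detail_image[:, ::-1])
        assert np.array_equal(out.context_mask, pair.context_mask[:, ::-1])

    def test_masks_stay_binary_across_many_draws(self, rng):
        pair = _toy_pair(rng)
        cfg = AugmentationConfig()
        r = np.random.default_rng(2)
        for _ in range(200):
            out = augment_pair(pair, cfg, r)
            assert set(np.unique(out.detail_mask)) <= {0, 1}
            assert set(np.unique(out.context_mask)) <= {0, 1}


@pytest.fixture(scope="module")
def tiny_ds(small_pairs):
    return dataset_from_pairs(small_pairs, "single_detail", downsample=7)


@pytest.fixture(scope="module")
def tiny_dual_ds(small_pairs):
    return dataset_from_pairs(small_pairs, "dual", downsample=7)


SCHED = TrainingSchedule(single_frozen_epochs=2, single_total_epochs=5,
                         dual_mca_only_epochs=2, dual_joint_epochs=2,
                         batch_size=4, scheduler_patience=2)


@pytest.fixture(scope="module")
def trained_singles(tiny_ds, small_pairs):
    cfg2 = default_config("mit", "test_tiny", "single_detail")
    cfg3 = default_config("mit", "test_tiny", "single_context")
    ds3 = dataset_from_pairs(small_pairs, "single_context", downsample=7)
    m2, b2, h2 = train_single(tiny_ds, cfg2, SCHED, seed=0)
    m3, _, _ = train_single(ds3, cfg3, SCHED, seed=1)
    return m2, m3, b2, h2


class TestTrainSingle:
    def test_history_and_best_epoch(self, trained_singles):
        _, _, best, hist = trained_singles
        assert len(hist) == SCHED.single_total_epochs
        assert best == int(np.argmin([h["val_loss"] for h in hist])) + 1

    def test_encoder_frozen_then_unfrozen(self, tiny_ds):
        cfg = default_config("mit", "test_tiny")
        checksums = []

        # run the frozen phase only and compare encoder checksums
        sched = TrainingSchedule(single_frozen_epochs=2, single_total_epochs=2,
                                 batch_size=4)
        from cgsnet.models import build_single
        ref = build_single(cfg, seed=7)
        enc_before = ref.encoder.checksum()
        model, _, _ = train_single(tiny_ds, cfg, sched, seed=7)
        assert model.encoder.checksum() == enc_before
        # and the decoder did move
        assert model.decoder.checksum() != ref.decoder.checksum()

    def test_training_loss_decreases(self, trained_singles):
        _, _, _, hist = trained_singles
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_empty_split_rejected(self, tiny_ds):
        bad = SegDataset(train_x=tiny_ds.train_x[:0], train_y=tiny_ds.train_y[:0],
                         val_x=tiny_ds.val_x, val_y=tiny_ds.val_y)
        with pytest.raises(ValueError):
            train_single(bad, default_config("mit", "test_tiny"), SCHED)


class TestTrainDual:
    def test_mca_only_phase_touches_only_mca(self, tiny_dual_ds, trained_singles):
        m2, m3, _, _ = trained_singles
        cfg = default_config("mit", "test_tiny", "dual")
        sched = TrainingSchedule(dual_mca_only_epochs=2, dual_joint_epochs=0,
                                 batch_size=4)
        model, _, hist = train_dual(tiny_dual_ds, (m2, m3), cfg, sched, seed=3)
        # encoders and decoder bitwise equal to their transfer sources
        assert model.encoder_detail.checksum() == m2.encoder.checksum()
        assert model.encoder_context.checksum() == m3.encoder.checksum()
        assert model.decoder.checksum() == m2.decoder.checksum()
        # MCA query weights moved away from zero
        q_norm = sum(float(np.abs(b.q.weight.data).sum())
                     for b in model.mca_blocks())
        assert q_norm > 0

    def test_epoch0_predictions_ignore_context(self, tiny_dual_ds,
                                               trained_singles):
        m2, m3, _, _ = trained_singles
        from cgsnet.models import build_cgsnet, transfer_weights
        cfg = default_config("mit", "test_tiny", "dual")
        dual = build_cgsnet(cfg, seed=5)
        transfer_weights(m2, m3, dual)
        dual.eval()
        x = tiny_dual_ds.val_x[:2]
        ctx = tiny_dual_ds.val_ctx[:2]
        out1 = dual(Tensor(x), Tensor(ctx)).data
        out2 = dual(Tensor(x), Tensor(ctx[::-1].copy())).data
        assert np.abs(out1 - out2).max() <= 1e-6

    def test_optimizer_groups_partition_parameters(self, trained_singles,
                                                   tiny_dual_ds):
        m2, m3, _, _ = trained_singles
        from cgsnet.models import build_cgsnet
        cfg = default_config("mit", "test_tiny", "dual")
        dual = build_cgsnet(cfg, seed=5)
        opt, scheds = optimizer_groups(dual, SCHED)
        assert len(opt.groups) == 4
        assert len(scheds) == 3
        ids = [id(p) for g in opt.groups for p in g["params"]]
        assert len(ids) == len(set(ids)) == len(dual.parameters())


class TestRetrainCombined:
    def test_requires_positive_best_epoch(self, tiny_ds):
        with pytest.raises(ValueError):
            retrain_combined(default_config("mit", "test_tiny"), tiny_ds, 0)

    def test_runs_exactly_best_epochs_on_union(self, tiny_ds):
        cfg = default_config("mit", "test_tiny")
        model, hist = retrain_combined(cfg, tiny_ds, 3, SCHED, seed=2)
        assert len(hist) == 3
        assert tiny_ds.union().train_x.shape[0] == (len(tiny_ds.train_x)
                                                    + len(tiny_ds.val_x))

    def test_full_retrain_reproduces_training_run(self, tiny_ds):
        """With the same seed and the full epoch budget, the retrain stage is
        the same deterministic computation as a direct training run on the
        union dataset."""
        cfg = default_config("mit", "test_tiny")
        union = tiny_ds.union()
        direct, _, _ = train_single(union, cfg, SCHED, seed=9)
        retrained, _ = retrain_combined(cfg, tiny_ds,
                                        SCHED.single_total_epochs, SCHED, seed=9)
        assert direct.checksum() == retrained.checksum()
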