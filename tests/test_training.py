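"""Dice loss, learning-rate schedule and the training loop."""

import numpy as np
import pytest

import gliounet as g
from gliounet.patch_sampler import training_patch_inventory
from gliounet.training import (
    TrainConfig,
    dice_loss,
    dice_loss_grad,
    lr_schedule,
    one_hot,
    train,
)


def brute_force_dice_loss(probs, truth, smooth=1e-5):
    """Independent per-voxel summation oracle for the soft Dice loss."""
    n, c = probs.shape[:2]
    total = 0.0
    for i in range(n):
        for cl in range(c):
            inter = 0.0
            psum = 0.0
            tsum = 0.0
            for v in range(probs[i, cl].size):
                p = float(probs[i, cl].flat[v])
                t = float(truth[i, cl].flat[v])
                inter += p * t
                psum += p
                tsum += t
            total += (2 * inter + smooth) / (psum + tsum + smooth)
    return 1.0 - total / (n * c)


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self, rng):
        t = one_hot(rng.integers(0, 4, (1, 6, 6, 6)))
        assert dice_loss(t, t) < 1e-4

    def test_total_miss_near_one(self):
        truth = one_hot(np.zeros((1, 6, 6, 6), np.int64))
        wrong = one_hot(np.full((1, 6, 6, 6), 2, np.int64))
        # classes 1 and 3 are absent from both -> their smoothed Dice is 1,
        # so the macro average sits at 0.5 for a complete class swap
        assert dice_loss(wrong, truth) == pytest.approx(0.5, abs=1e-3)
        # restricting attention to the two populated classes: total miss
        loss_populated = dice_loss(wrong[:, [0, 2]], truth[:, [0, 2]])
        assert loss_populated > 1.0 - 1e-3

    def test_uniform_probabilities_match_summation_oracle(self, rng):
        truth = one_hot(np.zeros((1, 5, 5, 5), np.int64))
        probs = np.full_like(truth, 0.25)
        assert dice_loss(probs, truth) == pytest.approx(
            brute_force_dice_loss(probs, truth), abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_patches_match_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(2, 4, 8, 8, 8))
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        truth = one_hot(rng.integers(0, 4, (2, 8, 8, 8)))
        assert dice_loss(probs, truth) == pytest.approx(
            brute_force_dice_loss(probs, truth), abs=1e-6)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            z = rng.normal(size=(1, 4, 6, 6, 6))
            probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            truth = one_hot(rng.integers(0, 4, (1, 6, 6, 6)))
            assert 0.0 <= dice_loss(probs, truth) <= 1.0

    def test_decreasing_in_overlap(self):
        # fixed mask sizes, growing overlap -> strictly smaller loss
        losses = []
        for overlap in (2, 4, 6, 8):
            probs = np.zeros((1, 4, 1, 1, 16), np.float32)
            truth = np.zeros_like(probs)
            truth[0, 1, 0, 0, :8] = 1
            truth[0, 0, 0, 0, 8:] = 1
            probs[0, 1, 0, 0, 8 - overlap:16 - overlap] = 1
            probs[0, 0, 0, 0, :8 - overlap] = 1
            probs[0, 0, 0, 0, 16 - overlap:] = 1
            losses.append(dice_loss(probs, truth))
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_gradient_matches_finite_differences(self, rng):
        probs = rng.random((1, 4, 4, 4, 4))
        truth = one_hot(rng.integers(0, 4, (1, 4, 4, 4)))
        grad = dice_loss_grad(probs, truth)
        eps = 1e-5
        for idx in [(0, 0, 1, 2, 3), (0, 2, 0, 0, 0), (0, 3, 3, 3, 3)]:
            p0 = probs[idx]
            probs[idx] = p0 + eps
            f1 = dice_loss(probs, truth)
            probs[idx] = p0 - eps
            f0 = dice_loss(probs, truth)
            probs[idx] = p0
            assert grad[idx] == pytest.approx((f1 - f0) / (2 * eps), rel=1e-3, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((1, 4, 2, 2, 2)), np.zeros((1, 4, 2, 2, 4)))


class TestSchedule:
    def test_initial_held_and_stepped_rates(self):
        cfg = TrainConfig()
        assert lr_schedule(1, cfg) == pytest.approx(0.001)
        assert lr_schedule(60, cfg) == pytest.approx(0.001)  # inclusive boundary
        assert lr_schedule(61, cfg) == pytest.approx(0.0001)
        assert lr_schedule(100, cfg) == pytest.approx(0.0001)

    def test_out_of_range_epoch_rejected(self):
        cfg = TrainConfig()
        for epoch in (0, 101, -3):
            with pytest.raises(ValueError, match="outside"):
                lr_schedule(epoch, cfg)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=-1.0)
        with pytest.raises(ValueError):
            TrainConfig(decay_factor=1.5)
        with pytest.raises(ValueError):
            TrainConfig(decay_epoch=100, epochs=100)


@pytest.fixture(scope="module")
def tiny_patchset():
    vol, labels = g.generate_phantom(g.PhantomConfig(shape=(48, 48, 48), rng_seed=11))
    mask = g.derive_brain_mask(vol)
    norm = g.zscore_normalize(vol, mask)
    return training_patch_inventory(norm, labels, mask, patch_size=16,
                                    rng_seed=0, max_boundary_patches=24)


class TestTrainLoop:
    def test_loss_decreases_and_history_length(self, tiny_patchset):
        net = g.build_unet(g.UNetConfig(levels=2, features=(4, 8)), seed=0)
        cfg = TrainConfig(lr=0.01, epochs=5, decay_epoch=4, rng_seed=0)
        _, history = train(net, tiny_patchset, cfg)
        assert len(history) == 5
        assert history[-1].mean_loss < history[0].mean_loss
        assert [h.epoch for h in history] == [1, 2, 3, 4, 5]

    def test_deterministic_given_seed(self, tiny_patchset):
        cfg = TrainConfig(lr=0.01, epochs=2, decay_epoch=1, rng_seed=4)
        losses = []
        for _ in range(2):
            net = g.build_unet(g.UNetConfig(levels=2, features=(4, 8)), seed=0)
            _, history = train(net, tiny_patchset, cfg)
            losses.append([h.mean_loss for h in history])
        assert losses[0] == losses[1]

    def test_empty_patchset_rejected(self):
        from gliounet.patch_sampler import PatchSet

        net = g.build_unet(g.UNetConfig(levels=2, features=(4, 8)), seed=0)
        empty = PatchSet([], np.empty((0, 4, 8, 8, 8), np.float32),
                         np.empty((0, 8, 8, 8), np.int16))
        with pytest.raises(ValueError, match="empty"):
            train(net, empty, TrainConfig())

    def test_history_csv(self, tmp_path, tiny_patchset):
        from gliounet.training import write_history_csv

        net = g.build_unet(g.UNetConfig(levels=2, features=(4, 8)), seed=0)
        _, history = train(net, tiny_patchset,
                           TrainConfig(lr=0.01, epochs=2, decay_epoch=1))
        path = write_history_csv(history, tmp_path / "log.csv")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "epoch,lr,mean_loss"
        assert len(lines) == 3
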