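"""Network: architecture arithmetic, gradients, sampling, loss, training plumbing."""

import numpy as np
import pytest

from aneuseg.network import (
    NetworkConfig,
    augment_flips,
    binarize,
    build_model,
    dice_loss,
    predict_volume,
    sample_patches,
    train_fold,
)
from aneuseg.network import autograd as ag
from aneuseg.network.inference import ProbabilityMap
from aneuseg.preprocess import ChannelStack
from aneuseg.volume import Volume3D

TINY = dict(
    segment_size=17,
    pathway_widths=(2, 2, 2, 2, 3, 3, 3, 3),
    fc_width=4,
    batch_size=4,
    epochs=1,
    batches_per_epoch=2,
)


def random_stack(shape=(24, 26, 22), channels=1, seed=0):
    rng = np.random.default_rng(seed)
    vols = [
        Volume3D(rng.random(shape).astype(np.float32), (0.5, 0.5, 0.5))
        for _ in range(channels)
    ]
    mask = Volume3D(np.ones(shape, dtype=np.uint8), (0.5, 0.5, 0.5))
    return ChannelStack(vols, "Orig" if channels == 1 else "Vess", mask=mask)


def random_labels(shape=(24, 26, 22), seed=1):
    rng = np.random.default_rng(seed)
    lab = np.zeros(shape, dtype=np.uint8)
    lab[8:14, 10:16, 8:14] = 1
    return Volume3D(lab, (0.5, 0.5, 0.5))


class TestArchitecture:
    def test_receptive_field_arithmetic(self):
        assert NetworkConfig(segment_size=25).out_window == 9
        assert NetworkConfig(segment_size=45).out_window == 29

    def test_segment_below_receptive_field_rejected(self):
        with pytest.raises(ValueError, match="17"):
            NetworkConfig(segment_size=15)
        with pytest.raises(ValueError, match="odd"):
            NetworkConfig(segment_size=18)

    def test_parameter_count_independent_of_seed(self):
        a = build_model(NetworkConfig(**TINY, seed=0))
        b = build_model(NetworkConfig(**TINY, seed=99))
        assert a.parameter_count() == b.parameter_count()

    def test_three_channel_config_accepted(self):
        model = build_model(NetworkConfig(**TINY, channels_in=3))
        cfg = model.config
        x_hi = np.zeros((1, 3) + (cfg.segment_size,) * 3)
        x_lo = np.zeros((1, 3) + (cfg.context_segment_size,) * 3)
        out = model.forward(x_hi, x_lo)
        assert out.shape == (1, 2) + (cfg.out_window,) * 3

    def test_channel_mismatch_rejected(self):
        model = build_model(NetworkConfig(**TINY, channels_in=1))
        with pytest.raises(ValueError, match="channel"):
            model.forward(np.zeros((1, 3, 17, 17, 17)), np.zeros((1, 3, 17, 17, 17)))


class TestGradients:
    def test_finite_difference_check(self):
        """Analytic gradients of the full forward+Dice graph match finite
        differences — the backbone correctness check for the hand-rolled net."""
        cfg = NetworkConfig(**TINY, dtype="float64", seed=0)
        model = build_model(cfg)
        rng = np.random.default_rng(1)
        x_hi = rng.standard_normal((2, 1) + (cfg.segment_size,) * 3)
        x_lo = rng.standard_normal((2, 1) + (cfg.context_segment_size,) * 3)
        y = (rng.random((2,) + (cfg.out_window,) * 3) < 0.5).astype(float)

        def loss():
            p = ag.foreground_prob(model.forward(x_hi, x_lo, training=True))
            return ag.soft_dice_loss(p, y, 1.0)

        model.zero_grad()
        loss().backward()
        eps = 1e-6
        for p in model.parameters()[::4]:
            flat, grad = p.data.ravel(), p.grad.ravel()
            for idx in np.random.default_rng(0).choice(
                flat.size, size=min(2, flat.size), replace=False
            ):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = float(loss().data)
                flat[idx] = orig - eps
                lm = float(loss().data)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = abs(numeric) + abs(grad[idx])
                assert abs(numeric - grad[idx]) <= max(1e-7, 1e-4 * denom)


class TestSampling:
    @pytest.mark.parametrize("segment", [25, 45])
    def test_segment_shapes(self, segment):
        cfg = NetworkConfig(
            segment_size=segment, pathway_widths=(2,) * 8, fc_width=4, batch_size=2
        )
        stack, labels = random_stack((50, 50, 50)), random_labels((50, 50, 50))
        pairs = sample_patches(stack, labels, cfg, n=4, seed=0)
        assert pairs[0].image_segment.shape == (1, segment, segment, segment)
        cs = cfg.context_segment_size
        assert pairs[0].context_segment.shape == (1, cs, cs, cs)
        assert pairs[0].label_segment.shape == (cfg.out_window,) * 3

    def test_foreground_centered_pairs(self):
        cfg = NetworkConfig(**TINY)
        stack, labels = random_stack(), random_labels()
        pairs = sample_patches(stack, labels, cfg, n=6, seed=3)
        w = cfg.out_window
        n_fg = int(round(6 * cfg.foreground_fraction))
        for pair in pairs[:n_fg]:
            assert pair.label_segment[w // 2, w // 2, w // 2] == 1

    def test_no_foreground_rejected(self):
        cfg = NetworkConfig(**TINY)
        stack = random_stack()
        empty = Volume3D(np.zeros((24, 26, 22), dtype=np.uint8), (0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="foreground"):
            sample_patches(stack, empty, cfg, n=4, seed=0)

    def test_deterministic(self):
        cfg = NetworkConfig(**TINY)
        stack, labels = random_stack(), random_labels()
        a = sample_patches(stack, labels, cfg, n=4, seed=7)
        b = sample_patches(stack, labels, cfg, n=4, seed=7)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.image_segment, pb.image_segment)


class TestFlips:
    def test_involution_and_label_count(self):
        cfg = NetworkConfig(**TINY)
        stack, labels = random_stack(), random_labels()
        pair = sample_patches(stack, labels, cfg, n=2, seed=0)[0]
        flipped = augment_flips(pair, seed=12)
        assert flipped.label_segment.sum() == pair.label_segment.sum()
        twice = augment_flips(flipped, seed=12)  # same seed -> same pattern
        assert np.array_equal(twice.image_segment, pair.image_segment)
        assert np.array_equal(twice.label_segment, pair.label_segment)

    def test_seeded_pattern_reproducible(self):
        cfg = NetworkConfig(**TINY)
        stack, labels = random_stack(), random_labels()
        pair = sample_patches(stack, labels, cfg, n=2, seed=0)[0]
        f1 = augment_flips(pair, seed=5)
        f2 = augment_flips(pair, seed=5)
        assert np.array_equal(f1.image_segment, f2.image_segment)


class TestDiceLoss:
    def test_perfect_and_complete_miss(self):
        t = np.array([[[1.0, 0.0], [0.0, 1.0]], [[1.0, 1.0], [0.0, 0.0]]])
        assert dice_loss(t, t, smooth=0.0) == pytest.approx(0.0)
        assert dice_loss(1 - t, t, smooth=0.0) == pytest.approx(1.0)

    def test_hand_summed_example(self):
        # 2³ patch, half foreground, uniform prediction 0.5, smooth 1:
        # inter = 0.5*4 = 2; denom = 4 + 4; loss = 1 - (2*2+1)/(8+1) = 4/9
        pred = np.full((2, 2, 2), 0.5)
        target = np.zeros((2, 2, 2))
        target[0] = 1.0
        assert dice_loss(pred, target, smooth=1.0) == pytest.approx(1 - 5 / 9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_bounded_for_probabilities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random((3, 3, 3))
            t = (rng.random((3, 3, 3)) < 0.5).astype(float)
            val = dice_loss(p, t, smooth=1.0)
            assert 0.0 <= val <= 1.0


class TestTraining:
    def test_one_epoch_plumbing_and_determinism(self):
        cfg = NetworkConfig(**TINY, seed=4)
        stack, labels = random_stack(), random_labels()
        m1 = train_fold([(stack, labels)], cfg)
        m2 = train_fold([(stack, labels)], NetworkConfig(**TINY, seed=4))
        assert len(m1.loss_log) == cfg.epochs
        assert m1.loss_log == m2.loss_log

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train_fold([], NetworkConfig(**TINY))


class TestInference:
    def test_output_grid_and_stability(self):
        cfg = NetworkConfig(**TINY, seed=1)
        model = build_model(cfg)
        stack = random_stack((20, 23, 19))
        p1 = predict_volume(model, stack, apply_mask=False)
        p2 = predict_volume(model, stack, apply_mask=False)
        assert p1.values.shape == (20, 23, 19)
        assert np.array_equal(p1.values, p2.values)
        assert p1.values.min() >= 0 and p1.values.max() <= 1

    def test_tiled_equals_single_pass(self):
        """Tiling the volume into small output windows must reproduce the
        whole-volume single-pass prediction exactly."""
        cfg = NetworkConfig(**TINY, seed=2)
        model = build_model(cfg)
        stack = random_stack((21, 24, 18))
        tiled = predict_volume(model, stack, tile=9, apply_mask=False)
        single = predict_volume(model, stack, tile=27, apply_mask=False)
        np.testing.assert_allclose(tiled.values, single.values, atol=1e-6)

    def test_checkpoint_roundtrip(self, tmp_path):
        from aneuseg.network.model import DualPathwayNet

        cfg = NetworkConfig(**TINY, seed=3)
        model = build_model(cfg)
        stack = random_stack((20, 20, 20))
        before = predict_volume(model, stack, apply_mask=False).values
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = DualPathwayNet.load(path)
        after = predict_volume(loaded, stack, apply_mask=False).values
        np.testing.assert_array_equal(before, after)


class TestBinarize:
    def test_thresholding(self):
        vol = Volume3D(np.array([[[0.0, 0.6, 0.99]]], dtype=np.float32), (1, 1, 1))
        pm = ProbabilityMap(volume=vol)
        assert binarize(pm, 0.5).values.tolist() == [[[0, 1, 1]]]
        assert binarize(pm, 1.0).values.sum() == 0
        empty = ProbabilityMap(volume=vol.with_values(np.zeros_like(vol.values)))
        assert binarize(empty).values.sum() == 0

    def test_threshold_range_enforced(self):
        vol = Volume3D(np.zeros((2, 2, 2), dtype=np.float32), (1, 1, 1))
        with pytest.raises(ValueError, match="threshold"):
            binarize(ProbabilityMap(volume=vol), 1.5)
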