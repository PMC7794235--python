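import dataclasses

import numpy as np
import pytest

from conftest import make_label, make_volume
from tbseg.errors import TrainingDivergenceError, ValidationError
from tbseg.preprocess import AugmentConfig
from tbseg.segnet import (
    NetConfig,
    TrainConfig,
    binarize,
    build_model,
    cross_validate,
    kfold_partition,
    learning_rate,
    load_model,
    predict,
    save_model,
    soft_dice_loss,
    soft_dice_loss_grad,
    train,
)
from tbseg.volgrid import isotropic_spec, resample

TINY_NET = NetConfig(depth=2, base_channels=4, patch_shape=(8, 8, 8))
QUIET_AUG = AugmentConfig(jitter_prob=0.0, flip_prob=0.0)


def quick_train_config(**kw):
    defaults = dict(
        epochs=2, initial_lr=1e-3, decay_every=400, folds=2, batch_size=1, augment=QUIET_AUG
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestSoftDiceLoss:
    def test_perfect_match_near_zero(self):
        r = np.zeros((2, 2, 2))
        r[0, 0, 0] = 1
        assert soft_dice_loss(r, r) <= 1e-4  # eps-order

    def test_all_zero_prediction(self):
        r = np.ones((2, 2, 2))
        assert soft_dice_loss(np.zeros_like(r), r) >= 1.0 - 1e-4

    def test_half_coverage_uniform_half(self):
        # p = 0.5 everywhere, reference covers half of an 8-voxel grid:
        # 1 - (2*0.25N)/(0.5N + 0.5N) = 0.5 as eps -> 0
        r = np.zeros((2, 2, 2))
        r[0] = 1.0
        p = np.full((2, 2, 2), 0.5)
        assert soft_dice_loss(p, r, eps=1e-12) == pytest.approx(0.5, abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            soft_dice_loss(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))

    def test_bounded(self, rng):
        for _ in range(10):
            p = rng.random((3, 3, 3))
            r = (rng.random((3, 3, 3)) < 0.5).astype(float)
            assert 0.0 <= soft_dice_loss(p, r) <= 1.0

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.1, 0.9, (3, 3, 3))
        r = (rng.random((3, 3, 3)) < 0.5).astype(float)
        loss, grad = soft_dice_loss_grad(p, r)
        h = 1e-6
        for idx in [(0, 0, 0), (1, 2, 1), (2, 2, 2)]:
            q = p.copy()
            q[idx] += h
            fd = (soft_dice_loss(q, r) - loss) / h
            assert fd == pytest.approx(grad[idx], rel=1e-3, abs=1e-9)


class TestNetConfig:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            NetConfig(depth=1)
        with pytest.raises(ValidationError):
            NetConfig(base_channels=2)
        with pytest.raises(ValidationError):
            NetConfig(depth=4, patch_shape=(12, 12, 12))  # not divisible by 8


class TestBuildAndPredict:
    def test_output_shape_and_range(self):
        model = build_model(NetConfig(depth=3, base_channels=8, patch_shape=(32, 32, 32)), seed=0)
        vol = make_volume(np.random.default_rng(0).random((32, 32, 32), dtype=np.float32))
        p = predict(model, vol)
        assert p.shape == (32, 32, 32)
        assert p.values.min() >= 0.0 and p.values.max() <= 1.0

    def test_seed_reproducible(self):
        vol = make_volume(np.random.default_rng(1).random((8, 8, 8), dtype=np.float32))
        a = predict(build_model(TINY_NET, seed=3), vol)
        b = predict(build_model(TINY_NET, seed=3), vol)
        np.testing.assert_array_equal(a.values, b.values)
        c = predict(build_model(TINY_NET, seed=4), vol)
        assert not np.array_equal(a.values, c.values)

    def test_predict_deterministic(self):
        model = build_model(TINY_NET, seed=0)
        vol = make_volume(np.random.default_rng(2).random((8, 8, 8), dtype=np.float32))
        np.testing.assert_array_equal(predict(model, vol).values, predict(model, vol).values)

    def test_all_air_gives_constant_output(self):
        # zero input + zero conv biases: every feature map is exactly
        # constant, so the head emits one value everywhere
        model = build_model(NetConfig(depth=3, base_channels=4, patch_shape=(16, 16, 16)), seed=0)
        vol = make_volume(np.zeros((16, 16, 16), dtype=np.float32))
        p = predict(model, vol).values
        assert np.allclose(p, p.flat[0])

    def test_predict_pads_awkward_grids(self):
        model = build_model(NetConfig(depth=3, base_channels=4, patch_shape=(16, 16, 16)), seed=0)
        vol = make_volume(np.random.default_rng(3).random((10, 13, 7), dtype=np.float32))
        assert predict(model, vol).shape == (10, 13, 7)

    def test_parameter_count_scales_quadratically(self):
        # analytic count for a 2-level plain net with c base channels:
        #   enc conv3 1->c, bottleneck conv3 c->2c, dec conv3 3c->c, head c->1
        def analytic(c):
            return (27 * 1 * c + c) + (27 * c * 2 * c + 2 * c) + (27 * 3 * c * c + c) + (c + 1)

        for c in (8, 16):
            cfg = NetConfig(depth=2, base_channels=c, patch_shape=(8, 8, 8))
            assert build_model(cfg, seed=0).net.n_parameters() == analytic(c)
        ratio = analytic(16) / analytic(8)
        assert 3.5 < ratio < 4.5

    def test_residual_variant_runs(self):
        cfg = NetConfig(depth=2, base_channels=4, patch_shape=(8, 8, 8), residual_blocks=True)
        model = build_model(cfg, seed=0)
        vol = make_volume(np.random.default_rng(4).random((8, 8, 8), dtype=np.float32))
        p = predict(model, vol)
        assert p.values.min() >= 0.0 and p.values.max() <= 1.0


class TestBinarize:
    def test_threshold(self):
        prob = make_volume(np.array([[[0.7, 0.3]]], dtype=np.float32))
        lab = binarize(prob, 0.5)
        assert lab.mask[0, 0, 0] and not lab.mask[0, 0, 1]

    def test_threshold_zero_all_ones(self, rng):
        prob = make_volume(rng.random((4, 4, 4), dtype=np.float32))
        assert binarize(prob, 0.0).voxel_count == 64

    def test_invalid_threshold(self, rng):
        prob = make_volume(rng.random((2, 2, 2), dtype=np.float32))
        with pytest.raises(ValidationError):
            binarize(prob, 1.5)

    def test_sweep_monotone(self, rng):
        prob = make_volume(rng.random((6, 6, 6), dtype=np.float32))
        counts = [binarize(prob, t).voxel_count for t in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestLearningRate:
    def test_paper_schedule_values(self):
        cfg = TrainConfig()  # 1e-4, third every 400
        assert learning_rate(cfg, 0) == 1e-4
        assert learning_rate(cfg, 400) == pytest.approx(1e-4 / 3)
        assert learning_rate(cfg, 800) == pytest.approx(1e-4 / 9)

    def test_piecewise_constant_with_expected_drops(self):
        cfg = TrainConfig(epochs=2000)
        lrs = [learning_rate(cfg, e) for e in range(cfg.epochs)]
        drops = sum(1 for a, b in zip(lrs, lrs[1:]) if b < a)
        assert drops == cfg.epochs // cfg.decay_every - (cfg.epochs % cfg.decay_every == 0)
        # within each 400-epoch window the lr is constant
        for start in range(0, 2000, 400):
            assert len(set(lrs[start : start + 400])) == 1


class TestTrain:
    def _toy_dataset(self, rng, n=2, size=8):
        data = []
        for _ in range(n):
            x = rng.random((size, size, size), dtype=np.float32)
            mask = np.zeros((size, size, size), dtype=np.uint8)
            mask[2:5, 2:5, 2:5] = 1
            x[mask.astype(bool)] = 0.9
            data.append((make_volume(x), make_label(mask)))
        return data

    def test_empty_dataset(self):
        with pytest.raises(ValidationError):
            train(build_model(TINY_NET, seed=0), [], quick_train_config())

    def test_zero_epochs_identity(self, rng):
        data = self._toy_dataset(rng)
        model = build_model(TINY_NET, seed=0)
        before = predict(model, data[0][0]).values.copy()
        model = train(model, data, quick_train_config(epochs=0))
        np.testing.assert_array_equal(predict(model, data[0][0]).values, before)

    def test_training_reproducible(self, rng):
        data = self._toy_dataset(rng)
        outs = []
        for _ in range(2):
            model = build_model(TINY_NET, seed=0)
            model = train(model, data, quick_train_config(epochs=3, seed=5))
            outs.append(predict(model, data[0][0]).values)
        np.testing.assert_allclose(outs[0], outs[1], atol=1e-5)

    def test_training_reduces_loss(self, rng):
        data = self._toy_dataset(rng)
        model = build_model(TINY_NET, seed=0)
        model = train(model, data, quick_train_config(epochs=30))
        losses = [l for l, _ in model.training_curve]
        assert losses[-1] < losses[0]

    def test_curve_recorded(self, rng):
        data = self._toy_dataset(rng)
        model = train(build_model(TINY_NET, seed=0), data, quick_train_config(epochs=4))
        assert len(model.training_curve) == 4

    def test_divergence_reported_with_epoch(self, rng):
        data = self._toy_dataset(rng)
        model = build_model(TINY_NET, seed=0)
        model.net.head.b[...] = np.nan  # poisons the pre-sigmoid logits
        with pytest.raises(TrainingDivergenceError) as exc:
            train(model, data, quick_train_config(epochs=1))
        assert exc.value.epoch == 0


class TestOverfitSmoke:
    def test_single_phantom_overfit(self, phantom_pair):
        # scaled-down version of the memorization check: one phantom at
        # 0.5 mm (32^3), 200 epochs of foreground-biased patch training
        from tbseg.metrics import dice
        from tbseg.preprocess import window_rescale

        vol, labels = phantom_pair
        v = window_rescale(vol)
        spec = isotropic_spec(v.grid, 0.5)
        v32 = resample(v, spec, "continuous")
        l32 = resample(labels["inner_ear"], spec, "nearest")
        cfg = NetConfig(depth=3, base_channels=8, patch_shape=(16, 16, 16))
        tc = TrainConfig(
            epochs=150, initial_lr=1e-3, decay_every=75, decay_factor=1 / 3,
            batch_size=1, seed=2, augment=QUIET_AUG, fg_crop_prob=0.7,
            patches_per_volume=8,
        )
        model = train(build_model(cfg, seed=2), [(v32, l32)], tc)
        pred = binarize(predict(model, v32), 0.5)
        assert dice(pred, l32) >= 0.95

        # loss trend: non-increasing across 50-epoch windows (local noise ok)
        losses = np.array([l for l, _ in model.training_curve])
        window_means = losses.reshape(3, 50).mean(axis=1)
        assert all(a >= b - 0.02 for a, b in zip(window_means, window_means[1:]))


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        model = build_model(TINY_NET, seed=1, structure_name="ossicles")
        model.training_curve = [(0.5, 0.5), (0.4, 0.6)]
        path = tmp_path / "m.ckpt.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.structure_name == "ossicles"
        assert back.net_config == model.net_config
        assert back.training_curve == [(0.5, 0.5), (0.4, 0.6)]
        vol = make_volume(rng.random((8, 8, 8), dtype=np.float32))
        np.testing.assert_array_equal(predict(back, vol).values, predict(model, vol).values)


class TestCrossValidate:
    def test_partition_properties(self):
        for n, folds in [(10, 5), (7, 3), (4, 4)]:
            parts = kfold_partition(n, folds, seed=1)
            assert len(parts) == folds
            flat = [i for p in parts for i in p]
            assert sorted(flat) == list(range(n))  # union = all, disjoint
            if folds == n:
                assert all(len(p) == 1 for p in parts)  # leave-one-out

    def test_folds_exceed_dataset(self):
        with pytest.raises(ValidationError):
            kfold_partition(3, 5)

    def test_cross_validate_structure(self, rng):
        data = []
        for _ in range(4):
            x = rng.random((8, 8, 8), dtype=np.float32)
            mask = np.zeros((8, 8, 8), dtype=np.uint8)
            mask[2:6, 2:6, 2:6] = 1
            x[mask.astype(bool)] = 0.9
            data.append((make_volume(x), make_label(mask)))
        results, mean = cross_validate(
            data, TINY_NET, quick_train_config(epochs=2, folds=2), structure_name="inner_ear"
        )
        assert len(results) == 2
        covered = sorted(i for r in results for i in r.test_indices)
        assert covered == [0, 1, 2, 3]
        assert set(mean) >= {"dsc_mean", "dsc_sd", "ahd_mm_mean"}
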