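"""Network construction, gradients, optimization schedule and inference."""

import numpy as np
import pytest

from bbsynth.bbnet import (
    Adam,
    NetworkConfig,
    TrainConfig,
    build_network,
    clip_gradients,
    fine_tune,
    infer,
    lr_at_epoch,
    sample_patches,
    train,
)
from bbsynth.bbnet.layers import BatchNorm3D, Conv3D
from bbsynth.bbnet.network import ResidualCNN3D
from bbsynth.preprocess import Volume3D


class TestBuildNetwork:
    def test_reference_architecture_structure(self):
        net = build_network(NetworkConfig(n_conv_layers=25, n_feature_maps=64), rng_seed=0)
        convs = [l for block in net.blocks for l in block if isinstance(l, Conv3D)] + [net.final]
        assert len(convs) == 25
        widths = [c.W.shape[-1] for c in convs]
        assert widths == [64] * 24 + [1]
        assert all(c.W.shape[:3] == (3, 3, 3) for c in convs)
        # batch norm after every conv except the final one
        bns = [l for block in net.blocks for l in block if isinstance(l, BatchNorm3D)]
        assert len(bns) == 24

    def test_too_shallow_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_conv_layers=1)

    def test_residual_identity_with_zero_final_layer(self, rng):
        net = build_network(NetworkConfig.desk_scale(), rng_seed=0)
        net.zero_final_layer()
        x = rng.random((2, 9, 11, 13)).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x), x)

    def test_arbitrary_shape_preserved(self, rng):
        net = build_network(NetworkConfig(n_conv_layers=3, n_feature_maps=4), rng_seed=0)
        x = rng.random((1, 40, 48, 56)).astype(np.float32)
        assert net.forward(x).shape == x.shape


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        cfg = NetworkConfig(n_conv_layers=3, n_feature_maps=4, use_batchnorm=False)
        net = build_network(cfg, rng_seed=2)
        x = rng.random((2, 6, 6, 6)).astype(np.float32)
        y = rng.random((2, 6, 6, 6)).astype(np.float32)

        def loss():
            out = net.forward(x, training=True)
            return float(np.mean((out.astype(np.float64) - y) ** 2))

        out = net.forward(x, training=True)
        diff = out - y
        net.backward((2.0 / diff.size) * diff)
        grads = [g.copy() for g in net.grads]
        check_rng = np.random.default_rng(0)
        for p, g in zip(net.params, grads):
            idx = tuple(check_rng.integers(0, s) for s in p.shape)
            if abs(g[idx]) < 1e-4:
                continue  # FD noise dominates near-zero gradients in float32
            eps = 1e-2
            old = p[idx]
            p[idx] = old + eps
            lp = loss()
            p[idx] = old - eps
            lm = loss()
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=0.1, abs=1e-4)

    def test_batchnorm_gradient_direction(self, rng):
        # one gradient step on gamma/beta must reduce the loss
        cfg = NetworkConfig(n_conv_layers=2, n_feature_maps=4)
        net = build_network(cfg, rng_seed=1)
        x = rng.random((4, 7, 7, 7)).astype(np.float32)
        y = (x * 0.5).astype(np.float32)
        out = net.forward(x, training=True)
        diff = out - y
        l0 = float(np.mean(diff**2))
        net.backward((2.0 / diff.size) * diff)
        for p, g in zip(net.params, net.grads):
            p -= 0.01 * g
        out1 = net.forward(x, training=True)
        assert float(np.mean((out1 - y) ** 2)) < l0


class TestSamplePatches:
    def test_colocated_patch_contract(self, rng):
        x = rng.random((96, 96, 96))
        y = x * 0.5
        cfg = TrainConfig(patch_size=31)
        X, Y, origins = sample_patches(x, y, cfg, n_patches=100, rng=0)
        assert X.shape == (100, 31, 31, 31) and Y.shape == X.shape
        for i in (0, 17, 99):
            ox, oy, oz = origins[i]
            np.testing.assert_allclose(X[i], x[ox:ox + 31, oy:oy + 31, oz:oz + 31])
            np.testing.assert_allclose(Y[i], X[i] * 0.5, rtol=1e-6)

    def test_fixed_seed_reproducible(self, rng):
        x = rng.random((64, 64, 64))
        cfg = TrainConfig(patch_size=31)
        _, _, o1 = sample_patches(x, x, cfg, n_patches=50, rng=7)
        _, _, o2 = sample_patches(x, x, cfg, n_patches=50, rng=7)
        np.testing.assert_array_equal(o1, o2)

    def test_volume_smaller_than_patch_rejected(self, rng):
        x = rng.random((16, 16, 16))
        with pytest.raises(ValueError, match="smaller than patch"):
            sample_patches(x, x, TrainConfig(patch_size=31), n_patches=5)

    def test_foreground_fraction_honored(self, rng):
        x = rng.random((64, 64, 64))
        fg = np.zeros((64, 64, 64), bool)
        fg[30:34, 30:34, 30:34] = True
        cfg = TrainConfig(patch_size=19, fg_min_fraction=0.8)
        X, _, origins = sample_patches(x, x, cfg, n_patches=50, fg_mask=fg, rng=3)
        hit = 0
        for ox, oy, oz in origins:
            if fg[ox:ox + 19, oy:oy + 19, oz:oz + 19].any():
                hit += 1
        assert hit >= 40


class TestSchedule:
    def test_step_decay_reaches_1e6_at_epoch_10(self):
        cfg = TrainConfig(learning_rate=1e-5)
        assert lr_at_epoch(cfg, 0) == pytest.approx(1e-5)
        assert lr_at_epoch(cfg, 9) == pytest.approx(1e-5)
        assert lr_at_epoch(cfg, 10) == pytest.approx(1e-6)
        assert lr_at_epoch(cfg, 20) == pytest.approx(1e-7)

    def test_gradient_clipped_to_unit_global_norm(self):
        grads = [np.full((10,), 5.0), np.full((10,), -5.0)]
        pre = clip_gradients(grads, 1.0)
        assert pre == pytest.approx(np.sqrt(20 * 25.0))
        post = np.sqrt(sum(float((g**2).sum()) for g in grads))
        assert post == pytest.approx(1.0, abs=1e-6)

    def test_small_gradients_unchanged(self):
        grads = [np.full((4,), 0.1)]
        clip_gradients(grads, 1.0)
        np.testing.assert_allclose(grads[0], 0.1)


class TestTraining:
    def test_overfits_single_patch_pair(self, rng):
        x = rng.random((1, 11, 11, 11)).astype(np.float32)
        y = np.clip(x - 0.5 * (x > 0.7), 0, 1).astype(np.float32)
        cfg = TrainConfig.desk_scale(batch_size=1, n_epochs=200, patience=10**9,
                                     lr_decay_every_epochs=200, patch_size=11, rng_seed=0)
        net = build_network(NetworkConfig(n_conv_layers=5, n_feature_maps=8,
                                          final_init_scale=0.0), rng_seed=5)
        mse0 = float(np.mean((net.forward(x) - y) ** 2))
        net, log = train(net, (x, y), cfg=cfg)
        mse1 = float(np.mean((net.forward(x) - y) ** 2))
        assert mse1 < 0.1 * mse0

    def test_lr_log_follows_schedule(self, rng):
        x = rng.random((4, 9, 9, 9)).astype(np.float32)
        cfg = TrainConfig(learning_rate=1e-5, n_epochs=12, batch_size=4, patch_size=9)
        net = build_network(NetworkConfig(n_conv_layers=2, n_feature_maps=2), rng_seed=0)
        _, log = train(net, (x, x), cfg=cfg)
        assert log.lr == [lr_at_epoch(cfg, e) for e in range(12)]
        assert log.stop_reason == "max_epochs"

    def test_validation_saturation_stops_early(self, rng):
        x = rng.random((6, 9, 9, 9)).astype(np.float32)
        cfg = TrainConfig(learning_rate=1e-12, n_epochs=30, batch_size=6,
                          patch_size=9, patience=2)
        net = build_network(NetworkConfig(n_conv_layers=2, n_feature_maps=2), rng_seed=0)
        _, log = train(net, (x, x), val_pairs=[(x, x)], cfg=cfg)
        assert log.stop_reason == "validation_saturation"
        assert len(log.train_loss) < 30

    def test_divergence_aborts_with_diagnostic(self, rng):
        net = build_network(NetworkConfig(n_conv_layers=2, n_feature_maps=2), rng_seed=0)
        net.final.W[:] = 1e38  # conv accumulation overflows float32 to inf
        x = rng.random((2, 9, 9, 9)).astype(np.float32)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(net, (x, x), cfg=TrainConfig(n_epochs=1, batch_size=2, patch_size=9))

    def test_fine_tune_starts_at_tenth_learning_rate(self, rng):
        x = rng.random((2, 9, 9, 9)).astype(np.float32)
        cfg = TrainConfig(learning_rate=1e-5, n_epochs=2, batch_size=2, patch_size=9)
        net = build_network(NetworkConfig(n_conv_layers=2, n_feature_maps=2), rng_seed=0)
        _, log = fine_tune(net, (x, x), cfg, n_epochs=2)
        assert log.lr[0] == pytest.approx(1e-6)

    def test_fine_tune_zero_epochs_is_noop(self, rng):
        net = build_network(NetworkConfig(n_conv_layers=2, n_feature_maps=2), rng_seed=0)
        before = [p.copy() for p in net.params]
        x = np.random.default_rng(0).random((2, 9, 9, 9)).astype(np.float32)
        net, log = fine_tune(net, (x, x), TrainConfig(), n_epochs=0)
        for b, p in zip(before, net.params):
            np.testing.assert_array_equal(b, p)
        assert log.stop_reason == "max_epochs"

    def test_training_deterministic_for_fixed_seed(self, rng):
        x = rng.random((4, 9, 9, 9)).astype(np.float32)
        y = (x * 0.8).astype(np.float32)
        cfg = TrainConfig.desk_scale(n_epochs=2, batch_size=2, patch_size=9, rng_seed=4)
        outs = []
        for _ in range(2):
            net = build_network(NetworkConfig(n_conv_layers=3, n_feature_maps=4), rng_seed=1)
            net, _ = train(net, (x.copy(), y.copy()), cfg=cfg)
            outs.append(net.forward(x))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestInference:
    def test_identity_network_round_trip(self, rng):
        net = build_network(NetworkConfig.desk_scale(), rng_seed=0)
        net.zero_final_layer()
        vol = Volume3D(rng.random((24, 24, 24)))
        out = infer(net, vol)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)
        assert out.modality == "DL_BB"

    def test_tiled_inference_matches_whole_volume(self, rng):
        net = build_network(NetworkConfig(n_conv_layers=3, n_feature_maps=4), rng_seed=3)
        # train-mode pass to move running statistics off their init
        net.forward(rng.random((1, 24, 24, 24)).astype(np.float32), training=True)
        vol = Volume3D(rng.random((40, 40, 40)))
        whole = infer(net, vol)
        tiled = infer(net, vol, tile_vox=24)
        np.testing.assert_allclose(tiled.data, whole.data, atol=1e-5)

    def test_output_finite(self, rng):
        net = build_network(NetworkConfig(n_conv_layers=3, n_feature_maps=4), rng_seed=0)
        out = infer(net, Volume3D(rng.random((20, 20, 20))))
        assert np.all(np.isfinite(out.data))

    def test_batchnorm_uses_running_statistics_at_test_time(self, rng):
        net = build_network(NetworkConfig(n_conv_layers=2, n_feature_maps=4), rng_seed=0)
        x = rng.random((2, 9, 9, 9)).astype(np.float32)
        net.forward(x, training=True)
        a = net.forward(x, training=False)
        b = net.forward(x, training=False)  # eval mode is stateless
        np.testing.assert_array_equal(a, b)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        net = build_network(NetworkConfig(n_conv_layers=3, n_feature_maps=4), rng_seed=9)
        x = rng.random((1, 12, 12, 12)).astype(np.float32)
        net.forward(x, training=True)  # populate running stats
        net.save(tmp_path / "model.npz")
        back = ResidualCNN3D.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(net.forward(x), back.forward(x))
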