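import time

import numpy as np
import pytest

import boxseg.nn
import boxseg.unet
from boxseg.unet import (
    VGG16_CONV_CHANNELS,
    UNet,
    UNetConfig,
    build_model,
    full_config,
    load_encoder_weights,
    sigmoid,
    tiny_config,
)


def _probe(net, size, seed=0):
    x = np.random.default_rng(seed).standard_normal((1, 3, size, size)).astype(np.float32)
    return sigmoid(net.forward(x, train=False))


class TestShapesAndRanges:
    def test_tiny_preset_output_matches_input_size(self):
        net = build_model(tiny_config(), seed=0)
        out = _probe(net, 96)
        assert out.shape == (1, 96, 96)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_depth_five_384_shape_contract(self):
        # depth-5 geometry of the full-size preset, narrow channels so the
        # forward pass stays cheap
        cfg = UNetConfig(depth=5, channel_schedule=(4, 4, 8, 8, 8),
                         convs_per_block=(1, 1, 1, 1, 1), bottleneck_channels=8,
                         input_size=384)
        net = build_model(cfg, seed=0)
        assert _probe(net, 384).shape == (1, 384, 384)

    def test_indivisible_input_raises(self):
        with pytest.raises(ValueError):
            UNetConfig(depth=3, input_size=100).validate()
        net = build_model(tiny_config(), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 3, 50, 50), dtype=np.float32))

    @pytest.mark.parametrize("seed", range(5))
    def test_constant_input_gives_finite_outputs(self, seed):
        net = build_model(tiny_config(), seed=seed)
        x = np.full((1, 3, 32, 32), 0.25, dtype=np.float32)
        out = net.forward(x, train=False)
        assert np.all(np.isfinite(out))

    def test_tiny_preset_is_desk_scale(self):
        net = build_model(tiny_config(), seed=0)
        assert net.num_params < 200_000
        x = np.zeros((1, 3, 96, 96), dtype=np.float32)
        net.forward(x, train=False)  # warm up
        best = min(
            (lambda t0: (net.forward(x, train=False), time.perf_counter() - t0)[1])(
                time.perf_counter()
            )
            for _ in range(10)
        )
        assert best < 0.050


class TestGradients:
    def test_backward_matches_numeric_gradient_in_float64(self, monkeypatch):
        monkeypatch.setattr(boxseg.nn, "DTYPE", np.float64)
        monkeypatch.setattr(boxseg.unet, "DTYPE", np.float64)
        cfg = UNetConfig(depth=2, channel_schedule=(4, 8), convs_per_block=(2, 1),
                         bottleneck_channels=8, input_size=8)
        net = UNet(cfg, seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 3, 8, 8))
        y = (rng.random((2, 8, 8)) > 0.5).astype(float)
        m = rng.random((2, 8, 8))

        def loss():
            p = np.clip(sigmoid(net.forward(x, train=False)), 1e-12, 1 - 1e-12)
            return float((m * -(y * np.log(p) + (1 - y) * np.log(1 - p))).sum() / m.sum())

        p = sigmoid(net.forward(x, train=True))
        net.backward(m * (p - y) / m.sum())
        check_rng = np.random.default_rng(2)
        for P, G in zip(net.params(), net.grads()):
            for _ in range(3):
                idx = tuple(check_rng.integers(0, s) for s in P.shape)
                eps, orig = 1e-6, P[idx]
                P[idx] = orig + eps
                lp = loss()
                P[idx] = orig - eps
                lm = loss()
                P[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert G[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestDeterminismAndPersistence:
    def test_same_seed_same_weights_and_predictions(self):
        a = build_model(tiny_config(), seed=7)
        b = build_model(tiny_config(), seed=7)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)
        assert np.array_equal(_probe(a, 32, seed=3), _probe(b, 32, seed=3))

    def test_checkpoint_round_trip(self, tmp_path):
        net = build_model(tiny_config(), seed=1)
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = UNet.load(path)
        assert np.array_equal(_probe(net, 32), _probe(loaded, 32))


class TestEncoderWeights:
    def test_random_source_is_seed_reproducible(self):
        a = build_model(tiny_config(), seed=0)
        b = build_model(tiny_config(), seed=1)
        load_encoder_weights(a, "random", seed=42)
        load_encoder_weights(b, "random", seed=42)
        for ca, cb in zip(a.encoder_convs(), b.encoder_convs()):
            assert np.array_equal(ca.W, cb.W)

    def test_checkpoint_source_restores_predictions(self, tmp_path):
        src = build_model(tiny_config(), seed=5)
        path = tmp_path / "ckpt.npz"
        src.save(path)
        dst = build_model(tiny_config(), seed=6)
        load_encoder_weights(dst, "checkpoint", weights_path=path)
        assert np.array_equal(_probe(src, 32), _probe(dst, 32))

    def test_vgg16_requires_matching_architecture(self):
        net = build_model(tiny_config(), seed=0)
        with pytest.raises(ValueError):
            load_encoder_weights(net, "vgg16-imagenet", weights_path="whatever.npz")

    def test_vgg16_requires_local_weights_and_loads_them(self, tmp_path):
        net = build_model(full_config(), seed=0)
        with pytest.raises(ValueError):
            load_encoder_weights(net, "vgg16-imagenet")  # no path, no download
        rng = np.random.default_rng(0)
        arrays = {}
        for i, (c_in, c_out) in enumerate(VGG16_CONV_CHANNELS):
            arrays[f"conv_{i}_W"] = rng.standard_normal((c_out, c_in, 3, 3)).astype(np.float32) * 0.01
            arrays[f"conv_{i}_b"] = np.zeros(c_out, dtype=np.float32)
        path = tmp_path / "vgg16_synthetic.npz"  # synthetic stand-in weights
        np.savez(path, **arrays)
        decoder_before = [u.W.copy() for u in net.ups]
        load_encoder_weights(net, "vgg16-imagenet", weights_path=path)
        for conv, i in zip(net.encoder_convs(), range(len(VGG16_CONV_CHANNELS))):
            assert np.array_equal(conv.W, arrays[f"conv_{i}_W"])
        for before, up in zip(decoder_before, net.ups):
            assert np.array_equal(before, up.W)  # decoder untouched

    def test_unknown_source_raises(self):
        with pytest.raises(ValueError):
            load_encoder_weights(build_model(tiny_config()), "imagenet21k")
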