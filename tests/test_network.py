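import numpy as np
import pytest

from histofusion import network as nw
from histofusion import synthetic
from histofusion.synthetic import ConfigurationError, DimensionError

# the published architecture table: (layer kind, shape after the layer)
TABLE_TRACE = [
    ("convolution", (134, 134, 32)),
    ("convolution", (128, 128, 32)),
    ("max_pool", (62, 62, 32)),
    ("convolution", (54, 54, 64)),
    ("max_pool", (25, 25, 64)),
    ("convolution", (19, 19, 64)),
    ("convolution", (13, 13, 128)),
    ("max_pool", (4, 4, 128)),
    ("convolution", (1, 1, 256)),
    ("full_connection", (1, 1, 256)),
    ("softmax", (1, 1, 6)),
]


class TestShapeArithmetic:
    @pytest.mark.parametrize(
        "n,k,s,p,expected",
        [
            (140, 7, 1, 0, 134),
            (134, 7, 1, 0, 128),
            (62, 9, 1, 0, 54),
            (25, 7, 1, 0, 19),
            (19, 7, 1, 0, 13),
            (4, 4, 1, 0, 1),
            (100, 1, 1, 0, 100),  # 1x1 kernel identity
            (10, 3, 1, 1, 10),  # same-padding case
        ],
    )
    def test_conv_output_size(self, n, k, s, p, expected):
        assert nw.conv_output_size(n, k, s, p) == expected

    @pytest.mark.parametrize(
        "n,w,s,expected",
        [(128, 5, 2, 62), (54, 5, 2, 25), (13, 6, 2, 4)],
    )
    def test_pool_output_size_floor_convention(self, n, w, s, expected):
        assert nw.pool_output_size(n, w, s) == expected

    def test_oversize_windows_rejected(self):
        with pytest.raises(DimensionError):
            nw.conv_output_size(5, 7, 1, 0)
        with pytest.raises(DimensionError):
            nw.pool_output_size(4, 5, 2)

    def test_default_trace_matches_architecture_table(self):
        cfg = nw.NetworkConfig()
        trace = cfg.shape_trace()
        assert len(trace) == 11
        for spec, (kind, shape) in zip(cfg.layers, TABLE_TRACE):
            assert spec.kind == kind
        assert trace == [shape for _, shape in TABLE_TRACE]

    def test_off_table_input_size_propagates(self):
        cfg = nw.NetworkConfig(input_size=141)
        assert cfg.shape_trace()[0] == (135, 135, 32)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            nw.NetworkConfig(input_size=30)  # collapses before the stack ends


class TestBuild:
    def test_parameter_shapes_match_trace(self):
        net = nw.build_network(nw.scaled_network_config(input_size=32), seed=0)
        trace = net.shape_trace()
        conv_i = [
            i for i, s in enumerate(net.config.layers) if s.kind == "convolution"
        ]
        for i in conv_i:
            spec = net.config.layers[i]
            W = net.layers[i].W
            assert W.shape[-1] == trace[i][2]
            assert W.shape[:2] == (spec.kernel, spec.kernel)

    def test_build_is_deterministic(self):
        cfg = nw.scaled_network_config(input_size=32)
        a = nw.build_network(cfg, seed=42)
        b = nw.build_network(cfg, seed=42)
        for (Wa, ba), (Wb, bb) in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(Wa, Wb)
            np.testing.assert_array_equal(ba, bb)

    def test_weights_scale_with_fan_in(self):
        net = nw.build_network(nw.NetworkConfig(), seed=0)
        for (W, b), spec in zip(
            net.parameters,
            [s for s in net.config.layers if s.kind != "max_pool"],
        ):
            fan_in = np.prod(W.shape[:-1])
            assert W.std() == pytest.approx(np.sqrt(2.0 / fan_in), rel=0.15)
            assert np.all(b == 0)


class TestLRN:
    def test_zero_input_maps_to_zero(self):
        x = np.zeros((4, 4, 8))
        np.testing.assert_array_equal(nw.local_response_normalization(x), x)

    def test_identity_when_alpha_zero_and_k_one(self):
        x = np.random.default_rng(0).random((3, 3, 1))
        out = nw.local_response_normalization(x, params=(0, 1.0, 0.0, 0.75))
        np.testing.assert_allclose(out, x)

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 4, 8))
        depth_radius, k, alpha, beta = 5, 2.0, 1e-4, 0.75
        half = depth_radius // 2
        expected = np.empty_like(x)
        for i in range(4):
            for j in range(4):
                for c in range(8):
                    lo, hi = max(0, c - half), min(8, c + half + 1)
                    s = float(np.sum(x[i, j, lo:hi] ** 2))
                    expected[i, j, c] = x[i, j, c] / (k + alpha * s) ** beta
        out = nw.local_response_normalization(x, params=(depth_radius, k, alpha, beta))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_non_finite_input_rejected(self):
        x = np.full((2, 2, 3), np.nan)
        with pytest.raises(FloatingPointError):
            nw.local_response_normalization(x)


class TestDropout:
    def test_rate_zero_and_inference_are_identity(self):
        x = np.random.default_rng(0).random(100)
        np.testing.assert_array_equal(nw.apply_dropout(x, 0.0, 1, True), x)
        np.testing.assert_array_equal(nw.apply_dropout(x, 0.7, 1, False), x)

    def test_zeroed_fraction_concentrates_at_rate(self):
        x = np.ones(10**6)
        out = nw.apply_dropout(x, 0.5, seed=2, training=True)
        assert np.mean(out == 0) == pytest.approx(0.5, abs=0.002)
        # survivors are scaled by 1/(1-rate)
        assert np.all(out[out != 0] == 2.0)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            nw.apply_dropout(np.ones(3), 1.0, 0, True)


class TestForward:
    def test_probability_rows_sum_to_one(self):
        net = nw.build_network(nw.scaled_network_config(input_size=32), seed=1)
        imgs = np.random.default_rng(0).random((5, 32, 32, 3)).astype(np.float32)
        probs = nw.predict_proba(net, list(imgs))
        assert probs.shape == (5, 6)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_zero_head_gives_uniform_probabilities(self):
        net = nw.build_network(nw.scaled_network_config(input_size=32), seed=1)
        net.layers[-1].W[:] = 0
        net.layers[-1].b[:] = 0
        img = np.random.default_rng(1).random((32, 32, 3)).astype(np.float32)
        np.testing.assert_allclose(nw.predict_proba(net, [img]), 1 / 6, atol=1e-12)

    def test_size_mismatch_rejected(self):
        net = nw.build_network(nw.scaled_network_config(input_size=32), seed=0)
        with pytest.raises(DimensionError):
            nw.predict_proba(net, [np.zeros((16, 16, 3))])


class TestBackprop:
    def test_loss_gradient_matches_central_differences(self):
        """Analytic backprop through conv+LRN+pool+conv+fc+softmax agrees
        with numerical differentiation (float64, sampled entries)."""
        C = nw.LayerSpec
        cfg = nw.NetworkConfig(
            input_size=8,
            layers=(
                C("convolution", kernel=3, out_channels=3, lrn=True),
                C("max_pool", kernel=2, stride=2),
                C("convolution", kernel=2, out_channels=4),
                C("full_connection", out_channels=5),
                C("softmax", out_channels=3),
            ),
            n_classes=3,
            dropout_rate=0.0,
        )
        net = nw.build_network(cfg, seed=1)
        for layer in net.layers:
            if hasattr(layer, "W"):
                layer.W = layer.W.astype(np.float64)
                layer.b = layer.b.astype(np.float64)
        rng = np.random.default_rng(2)
        X = rng.random((4, 8, 8, 3))
        y = np.eye(3)[rng.integers(0, 3, 4)]
        _, grads = nw.loss_gradients(net, X, y)
        h = 1e-6
        param_layers = [l for l in net.layers if hasattr(l, "W")]
        for li, layer in enumerate(param_layers):
            for G, name in zip(grads[li], ["W", "b"]):
                flat = getattr(layer, name).ravel()
                for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                    orig = flat[i]
                    flat[i] = orig + h
                    lp, _ = nw.loss_gradients(net, X, y)
                    flat[i] = orig - h
                    lm, _ = nw.loss_gradients(net, X, y)
                    flat[i] = orig
                    num = (lp - lm) / (2 * h)
                    ana = G.ravel()[i]
                    assert abs(num - ana) <= 1e-6 * max(1.0, abs(num) + abs(ana))


def _toy_dataset(n_per_class=12, seed=0, n_classes=3):
    """Linearly separable 32x32 colour blobs with light noise."""
    rng = np.random.default_rng(seed)
    colors = np.eye(3) * 0.6 + 0.2
    images, labels = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            img = np.tile(colors[c], (32, 32, 1)) + rng.normal(0, 0.05, (32, 32, 3))
            images.append(np.clip(img, 0, 1).astype(np.float32))
            labels.append(c + 1)
    ds = synthetic.ImageDataset(images=images, labels=np.asarray(labels))
    return synthetic.split_dataset(ds, (0.7, 0.15, 0.15), seed=seed)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        data = _toy_dataset()
        cfg = nw.scaled_network_config(input_size=32, n_classes=3)
        net = nw.build_network(cfg, seed=0)
        tc = nw.TrainConfig(batch_size=8, epochs=8, initial_lr=0.01, seed=0)
        nw.train_network(net, data, tc)
        hist = net.history["train_loss"]
        assert hist[-1] < hist[0]
        # smoothed loss decreases overall
        sm = np.convolve(hist, np.ones(3) / 3, mode="valid")
        assert sm[-1] < sm[0]

    def test_training_is_deterministic(self):
        data = _toy_dataset()
        cfg = nw.scaled_network_config(input_size=32, n_classes=3)
        tc = nw.TrainConfig(batch_size=8, epochs=2, seed=5)
        nets = []
        for _ in range(2):
            net = nw.build_network(cfg, seed=5)
            nw.train_network(net, data, tc)
            nets.append(net)
        for (Wa, _), (Wb, _) in zip(nets[0].parameters, nets[1].parameters):
            np.testing.assert_array_equal(Wa, Wb)

    def test_plateau_schedule_arithmetic(self):
        assert nw.plateau_lr(0.01, 2, 10.0) == pytest.approx(1e-4)

    def test_lr_drops_when_validation_stalls(self):
        """With patience 1 and hopeless (label-shuffled) data the recorded
        learning rate must fall by the drop factor at least once."""
        data = _toy_dataset(n_per_class=6, seed=1)
        rng = np.random.default_rng(0)
        data.labels = rng.permutation(data.labels)
        cfg = nw.scaled_network_config(input_size=32, n_classes=3)
        net = nw.build_network(cfg, seed=0)
        tc = nw.TrainConfig(
            batch_size=8, epochs=6, initial_lr=1e-6, plateau_patience=1, seed=0
        )
        nw.train_network(net, data, tc)
        assert min(net.history["lr"]) < 1e-6

    def test_memorizes_tiny_dataset(self):
        data = _toy_dataset(n_per_class=3, seed=2)
        cfg = nw.scaled_network_config(input_size=32, n_classes=3)
        net = nw.build_network(cfg, seed=1)
        tc = nw.TrainConfig(batch_size=4, epochs=30, initial_lr=0.02, seed=1)
        nw.train_network(net, data, tc)
        assert net.history["train_loss"][-1] < 0.2

    def test_missing_split_rejected(self):
        ds = synthetic.ImageDataset(
            images=[np.zeros((32, 32, 3), dtype=np.float32)], labels=np.array([1])
        )
        cfg = nw.scaled_network_config(input_size=32, n_classes=3)
        net = nw.build_network(cfg, seed=0)
        with pytest.raises(ConfigurationError):
            nw.train_network(net, ds, nw.TrainConfig(batch_size=1, epochs=1))


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path, tiny_trained):
        net, data = tiny_trained
        path = tmp_path / "model.npz"
        nw.save_network(net, path)
        back = nw.load_network(path)
        imgs = data.images[:4]
        np.testing.assert_allclose(
            nw.predict_proba(net, imgs), nw.predict_proba(back, imgs), atol=1e-7
        )
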