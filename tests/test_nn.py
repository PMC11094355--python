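"""The five network architectures: structure, training, prediction."""

import numpy as np
import pytest

from seedvigor import nn


def _layer_ops(spec):
    return [d["op"] for d in spec.layers]


class TestStructure:
    """Each built architecture's layer inventory, field by field."""

    def test_cnn2d_inventory(self):
        spec, _ = nn.build_model("cnn2d", (46, 46, 5))
        convs = [d for d in spec.layers if d["op"] == "conv2d"]
        pools = [d for d in spec.layers if d["op"] == "maxpool2d"]
        assert [c["kernel"] for c in convs] == [[5, 5], [5, 5]]
        assert [c["filters"] for c in convs] == [6, 16]
        assert [p["size"] for p in pools] == [[2, 2], [2, 2]]
        denses = [d for d in spec.layers if d["op"] == "dense"]
        assert denses[0] == {"op": "dense", "units": 120, "activation": "relu"}
        assert denses[1]["units"] == spec.n_classes
        assert spec.layers[-1]["op"] == "softmax"

    def test_cnn1d_inventory(self):
        spec, _ = nn.build_model("cnn1d", (360,))
        convs = [d for d in spec.layers if d["op"] == "conv1d"]
        pools = [d for d in spec.layers if d["op"] == "maxpool1d"]
        drops = [d for d in spec.layers if d["op"] == "dropout"]
        assert [c["kernel"] for c in convs] == [[1, 3], [1, 3]]
        assert [p["size"] for p in pools] == [[1, 2], [1, 2]]
        assert [d["rate"] for d in drops] == [0.2, 0.2]
        denses = [d for d in spec.layers if d["op"] == "dense"]
        assert denses[0]["units"] == 128 and denses[0]["activation"] == "relu"
        assert denses[1]["units"] == 4  # head narrows 128 -> 4
        ops = _layer_ops(spec)
        # a dropout immediately precedes each fully connected layer
        for i, op in enumerate(ops):
            if op == "dense":
                assert ops[i - 1] == "dropout" or ops[i - 2] == "dropout"
        assert ops[-1] == "softmax"

    def test_lstm1d_inventory(self):
        spec, _ = nn.build_model("lstm1d", (360,))
        ops = _layer_ops(spec)
        assert ops.count("lstm") == 1
        assert ops.count("dropout") == 2
        assert ops.count("dense") == 2
        assert ops.index("dropout") < ops.index("lstm")
        drops = [d for d in spec.layers if d["op"] == "dropout"]
        assert all(d["rate"] == 0.2 for d in drops)

    def test_lstm_image_inventory(self):
        spec, _ = nn.build_model("lstm_image", (46, 46, 5))
        ops = _layer_ops(spec)
        assert ops.count("lstm") == 3
        assert ops.count("batchnorm") == 1
        assert ops.count("dense") == 2
        # batch norm sits between the LSTM stack and the dense head
        assert max(i for i, o in enumerate(ops) if o == "lstm") \
            < ops.index("batchnorm") < min(i for i, o in enumerate(ops) if o == "dense")
        denses = [d for d in spec.layers if d["op"] == "dense"]
        assert denses[0]["activation"] == "elu"

    def test_cnn_lstm_inventory(self):
        spec, _ = nn.build_model("cnn_lstm", (46, 46, 5))
        ops = _layer_ops(spec)
        convs = [d for d in spec.layers if d["op"] == "conv2d"]
        assert [c["kernel"] for c in convs] == [[3, 3], [3, 3]]
        assert ops.count("lstm") == 2
        assert ops.count("batchnorm") == 1
        denses = [d for d in spec.layers if d["op"] == "dense"]
        assert denses[0] == {"op": "dense", "units": 128, "activation": "elu"}
        assert denses[1]["units"] == spec.n_classes
        # conv stack feeds the LSTMs, batch norm before the dense head
        assert max(i for i, o in enumerate(ops) if o == "conv2d") \
            < min(i for i, o in enumerate(ops) if o == "lstm")
        assert ops.index("batchnorm") < min(i for i, o in enumerate(ops) if o == "dense")

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            nn.build_model("transformer", (46, 46, 5))

    def test_incompatible_input_shape_rejected(self):
        with pytest.raises(ValueError):
            nn.build_model("cnn2d", (360,))
        with pytest.raises(ValueError):
            nn.build_model("cnn1d", (46, 46, 5))


class TestForward:
    @pytest.mark.parametrize("arch,shape", [
        ("cnn2d", (46, 46, 5)),
        ("cnn1d", (60,)),
        ("lstm1d", (30,)),
        ("lstm_image", (12, 10, 3)),
        ("cnn_lstm", (46, 46, 5)),
    ])
    def test_logits_shape_and_softmax_normalization(self, arch, shape):
        spec, model = nn.build_model(arch, shape, n_classes=4, rng_seed=0)
        x = np.random.default_rng(0).standard_normal((3,) + shape)
        labels, probs = nn.predict_labels(model, x)
        assert probs.shape == (3, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(labels, np.argmax(probs, axis=1))

    def test_gradients_match_finite_differences(self):
        """Backprop through conv/pool/LSTM/BN/dense agrees with numeric grads."""
        spec, net = nn.build_model("cnn_lstm", (10, 8, 2), n_classes=3,
                                   rng_seed=1, lstm_units=5)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 10, 8, 2))
        y = rng.integers(0, 3, 4)
        net.loss_and_grad(x, y)
        eps = 1e-6
        for p, g in net.params():
            flat_idx = np.random.default_rng(1).integers(0, p.size, 3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                l1, _ = net.loss_and_grad(x, y)
                p[idx] = orig - eps
                l2, _ = net.loss_and_grad(x, y)
                p[idx] = orig
                net.loss_and_grad(x, y)
                num = (l1 - l2) / (2 * eps)
                assert abs(num - g[idx]) <= 1e-4 * max(1.0, abs(num))

    def test_rows_as_timesteps_contract(self):
        """Any reshape honoring row=timestep, feature=(width x channels)
        produces identical LSTM inputs."""
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 6, 5, 3))
        layer = nn.RowsToSequence()
        seq = layer.forward(x, training=False)
        assert seq.shape == (2, 6, 15)
        manual = np.stack(
            [np.stack([x[n, t].reshape(-1) for t in range(6)]) for n in range(2)]
        )
        np.testing.assert_array_equal(seq, manual)


class TestTraining:
    def _easy_set(self, n=40, bands=24):
        rng = np.random.default_rng(3)
        y = np.arange(n) % 4
        X = rng.normal(0, 0.05, (n, bands))
        for i in range(n):
            X[i, y[i] * 6 : y[i] * 6 + 6] += 1.0  # class-coded blocks
        return X, y

    def test_capacity_reaches_perfect_training_accuracy(self):
        X, y = self._easy_set()
        spec, model = nn.build_model("cnn1d", (X.shape[1],), rng_seed=0)
        hp = nn.HyperParams(lr=0.005, bs=8, epochs=200, optimizer="adam")
        model, hist = nn.train_model(model, (X, y), None, hp, rng_seed=0)
        assert hist.train_accuracy[-1] == 100.0

    def test_zero_epochs_no_op(self):
        X, y = self._easy_set(n=8)
        spec, model = nn.build_model("cnn1d", (X.shape[1],), rng_seed=0)
        before = [p.copy() for p, _ in model.params()]
        model, hist = nn.train_model(
            model, (X, y), None, nn.HyperParams(epochs=0), rng_seed=0
        )
        assert hist.train_loss == [] and hist.train_accuracy == []
        for (p, _), b in zip(model.params(), before):
            np.testing.assert_array_equal(p, b)

    @pytest.mark.parametrize("optimizer", ["sgd", "adam"])
    def test_deterministic_under_seed(self, optimizer):
        X, y = self._easy_set(n=16)
        finals = []
        for _ in range(2):
            spec, model = nn.build_model("lstm1d", (X.shape[1],), rng_seed=5,
                                         lstm_units=8)
            hp = nn.HyperParams(lr=0.01, bs=4, epochs=3, optimizer=optimizer)
            model, _ = nn.train_model(model, (X, y), (X, y), hp, rng_seed=5)
            finals.append([p.copy() for p, _ in model.params()])
        for a, b in zip(*finals):
            np.testing.assert_array_equal(a, b)

    def test_history_lengths_and_ranges(self):
        X, y = self._easy_set(n=16)
        spec, model = nn.build_model("cnn1d", (X.shape[1],), rng_seed=1)
        hp = nn.HyperParams(lr=0.01, bs=4, epochs=5, optimizer="adam")
        model, hist = nn.train_model(model, (X, y), (X, y), hp, rng_seed=1)
        assert len(hist.train_loss) == len(hist.test_accuracy) == 5
        assert all(0.0 <= a <= 100.0 for a in hist.train_accuracy)

    def test_divergence_raises_with_epoch(self):
        X, y = self._easy_set(n=16)
        X = X * 1e3
        spec, model = nn.build_model("cnn1d", (X.shape[1],), rng_seed=0)
        hp = nn.HyperParams(lr=1.0, bs=4, epochs=50, optimizer="sgd")
        with pytest.raises(nn.DivergenceError):
            nn.train_model(model, (X, y), None, hp, rng_seed=0)

    def test_prediction_batch_size_independence(self):
        X, y = self._easy_set(n=12)
        spec, model = nn.build_model("cnn1d", (X.shape[1],), rng_seed=2)
        one_by_one = np.concatenate(
            [nn.predict_labels(model, X[i : i + 1])[0] for i in range(len(X))]
        )
        all_at_once, _ = nn.predict_labels(model, X)
        np.testing.assert_array_equal(one_by_one, all_at_once)

    def test_hyperparams_validation(self):
        with pytest.raises(ValueError):
            nn.HyperParams(lr=-1.0)
        with pytest.raises(ValueError):
            nn.HyperParams(bs=0)
        with pytest.raises(ValueError):
            nn.HyperParams(optimizer="rmsprop")
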