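import numpy as np
import pytest

from qmsdr import ConfigError, DimensionError, ModelConfig, init_model, train
from qmsdr.network import (
    AdamW,
    EarlyStopper,
    PlateauScheduler,
    ResponseNetwork,
    TransferLayer,
    default_layer_sizes,
)


def tiny_config(**kw):
    defaults = dict(
        n_genes=3, n_channels=1, layer_sizes=(3, 2, 2, 3, 2, 2),
        dropout_p=0.0, weight_decay=1e-3, seed=3,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestInitModel:
    def test_full_panel_layer_sizes(self):
        config = ModelConfig(n_genes=702, n_channels=4)
        model = init_model(config)
        assert config.layer_sizes == (2808, 512, 512, 2048, 36, 4)
        assert model.layers[0].block_shape == (702, 4)
        assert model.layers[0].W.shape == (702, 4, 4)

    def test_parameter_count_matches_closed_form(self):
        config = ModelConfig(n_genes=10, n_channels=1,
                             layer_sizes=(10, 4, 4, 8, 3, 2))
        model = init_model(config)
        sizes = [10, 4, 4, 8, 3, 2]
        expected = 10 * 1 * 1  # block weights: n_genes * x * x
        expected += sizes[0] + 2 * sizes[0]  # layer-1 bias + batchnorm gamma/beta
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            expected += fan_in * fan_out + fan_out + 2 * fan_out
        expected += sizes[-1] * 1 + 1  # output head
        assert model.n_parameters() == expected

    def test_same_seed_gives_identical_weights(self):
        a, b = init_model(tiny_config()), init_model(tiny_config())
        for k, v in a.parameters().items():
            np.testing.assert_array_equal(v, b.parameters()[k])

    def test_layer_size_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_genes=10, n_channels=2, layer_sizes=(10, 4, 4, 8, 3, 2))

    def test_dense_weight_is_block_diagonal(self):
        model = init_model(ModelConfig(n_genes=4, n_channels=2,
                                       layer_sizes=(8, 3, 3, 4, 3, 2)))
        dense = model.layers[0].dense_weight()
        gene_of = np.arange(8) // 2
        off_block = gene_of[:, None] != gene_of[None, :]
        assert np.all(dense[off_block] == 0.0)
        assert np.any(dense[~off_block] != 0.0)


class TestTransferLayer:
    def test_zero_weights_give_zero_output_with_unit_norm(self):
        rng = np.random.default_rng(0)
        layer = TransferLayer(3, 2, rng)
        layer.W[:] = 0.0
        layer.b[:] = 0.0
        out, _ = layer.forward(rng.random((5, 3)), training=False)
        np.testing.assert_allclose(out, 0.0)

    def test_hand_computed_forward_with_frozen_stats(self):
        rng = np.random.default_rng(0)
        layer = TransferLayer(2, 2, rng)
        layer.W = np.array([[0.5, -1.0], [0.25, 0.75]])
        layer.b = np.array([0.1, -0.2])
        layer.gamma = np.array([2.0, 0.5])
        layer.beta = np.array([0.3, -0.1])
        layer.running_mean = np.array([0.05, -0.02])
        layer.running_var = np.array([0.4, 0.9])
        x = np.array([[1.0, -2.0]])
        z = x @ layer.W + layer.b
        expected = layer.gamma * (np.tanh(z) - layer.running_mean) / np.sqrt(
            layer.running_var + layer.bn_eps
        ) + layer.beta
        out, _ = layer.forward(x, training=False)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_pre_norm_activation_bounded_by_tanh(self):
        rng = np.random.default_rng(1)
        layer = TransferLayer(4, 3, rng)
        _, cache = layer.forward(rng.normal(size=(20, 4)) * 10, training=False)
        assert np.all(np.abs(cache["t"]) < 1.0)

    def test_shape_mismatch_raises(self):
        layer = TransferLayer(3, 2, np.random.default_rng(0))
        with pytest.raises(DimensionError):
            layer.forward(np.zeros((4, 5)), training=False)


class TestForward:
    def test_zeroed_network_predicts_output_bias(self):
        model = init_model(tiny_config())
        for name, p in model.parameters().items():
            if name != "head.b":
                p[...] = 0.0
        model.head_b[:] = 0.37
        # beta=0, gamma=0 => hidden all zero => prediction = head bias
        preds = model.predict(np.random.default_rng(0).random((6, 3)))
        np.testing.assert_allclose(preds, 0.37)

    def test_sample_permutation_equivariance(self):
        model = init_model(tiny_config())
        X = np.random.default_rng(0).random((8, 3))
        perm = np.random.default_rng(1).permutation(8)
        np.testing.assert_allclose(model.predict(X)[perm], model.predict(X[perm]))

    def test_manual_chain_on_three_gene_toy(self):
        config = tiny_config(layer_sizes=(3, 2, 2, 3, 2, 2))
        model = init_model(config)
        X = np.array([[0.2, 0.9, 0.4]])
        h = X
        for layer in model.layers:
            z = h @ layer.dense_weight() + layer.b
            t = np.tanh(z)
            h = layer.gamma * (t - layer.running_mean) / np.sqrt(
                layer.running_var + layer.bn_eps
            ) + layer.beta
        expected = (h @ model.head_W + model.head_b).ravel()
        np.testing.assert_allclose(model.predict(X), expected, atol=1e-10)

    def test_inference_is_deterministic_bitwise(self):
        model = init_model(tiny_config(dropout_p=0.5))
        X = np.random.default_rng(0).random((5, 3))
        np.testing.assert_array_equal(model.predict(X), model.predict(X))

    def test_wrong_channel_count_rejected(self):
        model = init_model(tiny_config())
        with pytest.raises(DimensionError):
            model.predict(np.zeros((4, 7)))


class TestBlockStructure:
    def test_zeroing_one_gene_only_touches_its_block(self):
        config = ModelConfig(n_genes=5, n_channels=2,
                             layer_sizes=(10, 4, 4, 6, 3, 2), dropout_p=0.0, seed=0)
        model = init_model(config)
        rng = np.random.default_rng(2)
        X = rng.random((6, 10))
        X_masked = X.copy()
        X_masked[:, 2:4] = 0.0  # zero gene 1's two channels
        layer = model.layers[0]
        h_full, _ = layer.forward(X, training=False)
        h_masked, _ = layer.forward(X_masked, training=False)
        changed = np.any(h_full != h_masked, axis=0)
        assert changed[2:4].any()
        assert not changed[:2].any() and not changed[4:].any()


class TestGradients:
    def test_parameter_and_input_gradients_match_finite_differences(self):
        model = init_model(tiny_config())
        assert model.n_parameters() <= 100
        rng = np.random.default_rng(0)
        X = rng.random((8, 3))
        y = rng.random(8)
        _, grads, dX = model.objective_and_grads(X, y, training=True)
        h = 1e-5

        def objective():
            obj, _, _ = model.objective_and_grads(X, y, training=True)
            return obj

        for name, p in model.parameters().items():
            for idx in np.ndindex(p.shape):
                orig = p[idx]
                p[idx] = orig + h
                up = objective()
                p[idx] = orig - h
                down = objective()
                p[idx] = orig
                fd = (up - down) / (2 * h)
                rel = abs(fd - grads[name][idx]) / max(1e-8, abs(fd) + abs(grads[name][idx]))
                assert rel < 1e-3, f"{name}{idx}: fd={fd} analytic={grads[name][idx]}"
        for idx in np.ndindex(X.shape):
            orig = X[idx]
            X[idx] = orig + h
            up = objective()
            X[idx] = orig - h
            down = objective()
            X[idx] = orig
            fd = (up - down) / (2 * h)
            rel = abs(fd - dX[idx]) / max(1e-8, abs(fd) + abs(dX[idx]))
            assert rel < 1e-3


class TestSchedulesAndStopping:
    def test_plateau_scheduler_cuts_lr_by_factor_after_patience(self):
        sched = PlateauScheduler(lr0=0.014, factor=0.2, patience=10, eps=1e-4)
        lr = sched.update(1.0)  # first value establishes the best
        for _ in range(9):
            lr = sched.update(1.0)
        assert lr == pytest.approx(0.014)
        lr = sched.update(1.0)  # 10th epoch without improvement
        assert lr == pytest.approx(0.0028)

    def test_scheduler_resets_on_improvement(self):
        sched = PlateauScheduler(lr0=0.014, factor=0.2, patience=3, eps=1e-4)
        sched.update(1.0)
        sched.update(1.0)
        sched.update(0.5)  # improvement resets the wait counter
        for _ in range(2):
            assert sched.update(0.5) == pytest.approx(0.014)
        assert sched.update(0.5) == pytest.approx(0.0028)

    def test_early_stopper_fires_exactly_at_patience(self):
        stopper = EarlyStopper(patience=20, eps=1e-4)
        assert not stopper.update(1.0)  # best epoch (epoch 0)
        fired_at = None
        for epoch in range(1, 40):
            if stopper.update(1.0):
                fired_at = epoch
                break
        assert fired_at == 20
        assert stopper.best_epoch == 0

    def test_sub_epsilon_improvement_does_not_reset(self):
        stopper = EarlyStopper(patience=2, eps=1e-4)
        stopper.update(1.0)
        stopper.update(1.0 - 5e-5)  # below eps: no reset
        assert stopper.update(1.0 - 9e-5)


class TestTraining:
    @staticmethod
    def _toy_problem(n=240, seed=0):
        # noiseless linear response to one gene's feature
        rng = np.random.default_rng(seed)
        X = rng.random((n, 4))
        y = 0.8 * X[:, 1]
        return X[:180], y[:180], X[180:], y[180:]

    def test_converges_on_noiseless_linear_toy(self):
        Xtr, ytr, Xv, yv = self._toy_problem()
        config = ModelConfig(
            n_genes=4, n_channels=1, layer_sizes=(4, 8, 8, 16, 8, 4),
            dropout_p=0.0, weight_decay=0.0, lr0=0.003, seed=0, max_epochs=300,
        )
        model, history = train(init_model(config), Xtr, ytr, Xv, yv)
        assert min(history.train_mse) < 0.01

    def test_lr_drops_to_0028_on_first_plateau_and_stops_20_after_best(self):
        Xtr, ytr, Xv, yv = self._toy_problem()
        config = ModelConfig(
            n_genes=4, n_channels=1, layer_sizes=(4, 8, 8, 16, 8, 4),
            dropout_p=0.0, weight_decay=0.0, seed=1, max_epochs=500,
        )
        model, history = train(init_model(config), Xtr, ytr, Xv, yv)
        assert history.stop_reason == "early_stop"
        assert history.stopped_epoch == history.best_epoch + 20
        lrs = history.learning_rates
        assert lrs[0] == pytest.approx(0.014)
        dropped = [lr for lr in lrs if lr < 0.014]
        assert dropped and dropped[0] == pytest.approx(0.0028)

    def test_restored_weights_reproduce_best_validation_loss(self):
        Xtr, ytr, Xv, yv = self._toy_problem(seed=3)
        config = ModelConfig(
            n_genes=4, n_channels=1, layer_sizes=(4, 8, 8, 16, 8, 4),
            dropout_p=0.1, weight_decay=1e-4, seed=2, max_epochs=120,
        )
        model, history = train(init_model(config), Xtr, ytr, Xv, yv)
        val = float(((model.predict(Xv) - yv) ** 2).mean())
        assert val == pytest.approx(min(history.val_mse), abs=1e-9)

    def test_checkpoint_round_trip(self, tmp_path):
        model = init_model(tiny_config())
        X = np.random.default_rng(0).random((4, 3))
        path = tmp_path / "model.npz"
        model.save(path, metadata={"drug": "d1"})
        loaded, meta = ResponseNetwork.load(path)
        np.testing.assert_array_equal(model.predict(X), loaded.predict(X))
        assert meta == {"drug": "d1"}


class TestAdamW:
    def test_decay_only_applies_to_declared_keys(self):
        params = {"W": np.array([10.0]), "b": np.array([10.0])}
        opt = AdamW(params, lr=0.1, weight_decay=0.5, decay_keys={"W"})
        opt.step({"W": np.zeros(1), "b": np.zeros(1)})
        assert params["W"][0] == pytest.approx(10.0 * (1 - 0.1 * 0.5))
        assert params["b"][0] == pytest.approx(10.0)
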