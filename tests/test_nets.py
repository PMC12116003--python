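"""Recurrent-network contracts: parameter counts, gradients, training behaviour."""

import numpy as np
import pandas as pd
import pytest

import vo2arm as v
from vo2arm.nets import (
    ModelConfig,
    _Network,
    rnn_layer_param_count,
    load_model,
    save_model,
)


class TestParameterCounts:
    @pytest.mark.parametrize(
        "arch,gates", [("lstm", 4), ("gru", 3)]
    )
    def test_unidirectional_gate_arithmetic(self, arch, gates):
        d, h = 7, 5
        net = _Network(
            ModelConfig(arch=arch, recurrent_units=h, n_recurrent_layers=1,
                        dense_units=3, seed=0),
            n_features=d,
        )
        layer_params = sum(p.size for p in net.recurrent[0].params())
        assert layer_params == gates * (d * h + h * h + h)
        assert layer_params == rnn_layer_param_count(arch, d, h)

    def test_bidirectional_doubles_weights(self):
        d, h = 7, 5
        uni = _Network(
            ModelConfig(arch="lstm", recurrent_units=h, n_recurrent_layers=1, seed=0),
            n_features=d,
        )
        bi = _Network(
            ModelConfig(arch="bilstm", recurrent_units=h, n_recurrent_layers=1, seed=0),
            n_features=d,
        )
        uni_n = sum(p.size for p in uni.recurrent[0].params())
        bi_n = sum(p.size for p in bi.recurrent[0].params())
        assert bi_n == 2 * uni_n
        assert rnn_layer_param_count("bilstm", d, h) == bi_n

    def test_bilstm_never_smaller_than_lstm(self):
        for d, h in [(3, 2), (10, 8), (69, 32)]:
            assert rnn_layer_param_count("bilstm", d, h) >= rnn_layer_param_count(
                "lstm", d, h
            )


class TestGradients:
    @pytest.mark.parametrize("arch", ["lstm", "bilstm", "gru"])
    def test_backprop_matches_numeric_gradient(self, arch):
        """Central-difference check of the full network gradient (no dropout)."""
        rng = np.random.default_rng(0)
        cfg = ModelConfig(
            arch=arch, recurrent_units=4, n_recurrent_layers=2, dense_units=3,
            dropout=0.0, seed=1,
        )
        net = _Network(cfg, n_features=3)
        X = rng.normal(size=(5, 4, 3))
        y = rng.normal(size=5)

        def loss():
            pred, _ = net.forward(X)
            return float(np.mean((pred - y) ** 2))

        pred, cache = net.forward(X)
        grads = net.backward(2.0 * (pred - y) / len(y), cache)
        params = net.params()
        eps = 1e-6
        checked = 0
        for p, g in zip(params, grads):
            flat_idx = rng.choice(p.size, size=min(4, p.size), replace=False)
            for idx in flat_idx:
                orig = p.flat[idx]
                p.flat[idx] = orig + eps
                up = loss()
                p.flat[idx] = orig - eps
                down = loss()
                p.flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert g.flat[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked >= 20


class TestTraining:
    def _linear_data(self, n=32, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, 3))
        y = 2.0 * X[:, 0] + 0.5
        return X, y

    def test_overfits_deterministic_linear_map(self):
        X, y = self._linear_data()
        model = v.RecurrentVO2Regressor(
            arch="lstm", recurrent_units=16, dense_units=16, dropout=0.0,
            batch_size=8, max_epochs=200, patience=200, val_fraction=0.2, seed=0,
        )
        model.fit(X, y)
        assert model.history_["train_mse"].iloc[-1] < 1e-2

    def test_patience_zero_stops_after_first_non_improvement(self):
        X, y = self._linear_data(n=40, seed=1)
        model = v.RecurrentVO2Regressor(
            recurrent_units=4, dense_units=4, dropout=0.3, batch_size=8,
            max_epochs=100, patience=0, seed=2,
        )
        model.fit(X, y)
        history = model.history_
        if len(history) < 100:  # early stop fired
            assert len(history) == model.best_epoch_ + 2

    def test_seeded_determinism(self):
        X, y = self._linear_data(n=48, seed=3)
        losses = []
        for _ in range(2):
            m = v.RecurrentVO2Regressor(
                recurrent_units=8, dense_units=8, batch_size=16, max_epochs=5,
                patience=5, seed=7,
            )
            m.fit(X, y)
            losses.append(m.history_["val_mse"].iloc[-1])
        assert losses[0] == losses[1]

    def test_best_epoch_beats_every_later_epoch(self):
        X, y = self._linear_data(n=60, seed=4)
        m = v.RecurrentVO2Regressor(
            recurrent_units=8, dense_units=8, batch_size=16, max_epochs=30,
            patience=6, seed=5,
        )
        m.fit(X, y)
        val = m.history_["val_mse"].to_numpy()
        assert np.all(val[m.best_epoch_] <= val[m.best_epoch_ :] + 1e-12)

    def test_training_loss_trend_decreases_on_noise_free_map(self):
        X, y = self._linear_data(n=64, seed=6)
        m = v.RecurrentVO2Regressor(
            recurrent_units=16, dense_units=16, dropout=0.0, batch_size=16,
            max_epochs=40, patience=40, seed=8,
        )
        m.fit(X, y)
        tr = m.history_["train_mse"].to_numpy()
        assert tr[-5:].mean() < tr[:5].mean()


class TestPredict:
    def test_inference_deterministic_and_pure(self):
        X, y = np.random.default_rng(0).normal(size=(30, 4)), np.arange(30.0)
        m = v.RecurrentVO2Regressor(
            recurrent_units=4, dense_units=4, batch_size=8, max_epochs=2, seed=0
        )
        m.fit(X, y)
        a, b = m.predict(X), m.predict(X)
        np.testing.assert_array_equal(a, b)
        const = np.tile(X[0], (7, 1))
        np.testing.assert_allclose(m.predict(const), m.predict(const)[0])

    def test_feature_width_mismatch_rejected(self):
        X = np.random.default_rng(1).normal(size=(20, 4))
        m = v.RecurrentVO2Regressor(
            recurrent_units=4, dense_units=4, max_epochs=1, batch_size=8, seed=0
        )
        m.fit(X, np.arange(20.0))
        with pytest.raises(ValueError, match="features"):
            m.predict(X[:, :3])

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="arch"):
            v.RecurrentVO2Regressor(arch="transformer", max_epochs=1).fit(
                np.zeros((4, 2)), np.zeros(4)
            )

    def test_checkpoint_round_trip(self, tmp_path):
        X, y = np.random.default_rng(2).normal(size=(24, 3)), np.arange(24.0)
        m = v.RecurrentVO2Regressor(
            recurrent_units=4, dense_units=4, max_epochs=2, batch_size=8, seed=1
        )
        m.fit(X, y)
        save_model(m, tmp_path / "ckpt")
        loaded = load_model(tmp_path / "ckpt")
        np.testing.assert_allclose(loaded.predict(X), m.predict(X), atol=1e-12)


class TestGridSearch:
    def test_picks_lowest_validation_candidate(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, size=(60, 2))
        y = X[:, 0] * 3.0
        configs = [
            ModelConfig(arch="lstm", recurrent_units=u, dense_units=8, dropout=0.0,
                        batch_size=16, max_epochs=15, patience=15, seed=1)
            for u in (2, 16)
        ]
        best, summary = v.grid_search(configs, X, y)
        assert len(summary) == 2
        assert best.history_["val_mse"].min() == summary["val_mse"].min()

    def test_rejects_oversized_grids(self):
        with pytest.raises(ValueError):
            v.grid_search([ModelConfig()] * 9, np.zeros((4, 1)), np.zeros(4))


class TestReshape:
    def test_seq_len_one_is_identity(self):
        X = np.arange(20.0).reshape(10, 2)
        X3, y, sids = v.reshape_for_sequence(X, np.arange(10.0), ["a"] * 10, 1)
        assert X3.shape == (10, 1, 2)
        np.testing.assert_array_equal(X3[:, 0, :], X)
        np.testing.assert_array_equal(y, np.arange(10.0))

    def test_floor_division_sample_count(self):
        X = np.zeros((100, 3))
        X3, y, _ = v.reshape_for_sequence(X, np.arange(100.0), ["a"] * 100, 5)
        assert X3.shape == (20, 5, 3)
        np.testing.assert_array_equal(y, np.arange(4.0, 100.0, 5.0))

    def test_sequences_never_span_subjects(self):
        sids = ["a"] * 7 + ["b"] * 9
        X = np.arange(16.0)[:, None]
        X3, y, out_sids = v.reshape_for_sequence(X, np.arange(16.0), sids, 4)
        # a contributes floor(7/4)=1 sample from its own rows only
        assert list(out_sids) == ["a", "b", "b"]
        np.testing.assert_array_equal(X3[0, :, 0], [0, 1, 2, 3])
        np.testing.assert_array_equal(X3[1, :, 0], [7, 8, 9, 10])

    def test_seq_len_longer_than_subject_rejected(self):
        with pytest.raises(ValueError, match="seq_len"):
            v.reshape_for_sequence(np.zeros((5, 2)), np.zeros(5), ["a"] * 5, 9)
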