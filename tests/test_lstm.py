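"""LSTM cell, stack, and training contracts."""

import numpy as np
import pytest

import shockwatch as sw
from shockwatch.lstm import (GATE_ORDER, LSTMCellWeights, LSTMClassifier,
                             LSTMState, ModelConfig, Sequence, lstm_cell_step)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def naive_cell_step(x, c_prev, h_prev, w: LSTMCellWeights):
    """Independent element-by-element evaluation of the gate formulas,
    written without reusing any production code paths."""
    units = len(c_prev)
    f = np.empty(units)
    i = np.empty(units)
    o = np.empty(units)
    g = np.empty(units)
    for j in range(units):
        f[j] = _sigmoid(np.dot(x, w.W_f[:, j]) + np.dot(h_prev, w.U_f[:, j])
                        + w.b_f[j])
        i[j] = _sigmoid(np.dot(x, w.W_i[:, j]) + np.dot(h_prev, w.U_i[:, j])
                        + w.b_i[j])
        o[j] = _sigmoid(np.dot(x, w.W_o[:, j]) + np.dot(h_prev, w.U_o[:, j])
                        + w.b_o[j])
        g[j] = np.tanh(np.dot(x, w.W_c[:, j]) + np.dot(h_prev, w.U_c[:, j])
                       + w.b_c[j])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return c, h


def random_weights(rng, n_in, units):
    def m(shape):
        return rng.normal(0, 0.5, shape)
    return LSTMCellWeights(
        W_f=m((n_in, units)), W_i=m((n_in, units)), W_o=m((n_in, units)),
        W_c=m((n_in, units)),
        U_f=m((units, units)), U_i=m((units, units)), U_o=m((units, units)),
        U_c=m((units, units)),
        b_f=m(units), b_i=m(units), b_o=m(units), b_c=m(units),
    )


class TestCellStep:
    def test_zero_weights_zero_state(self):
        w = random_weights(np.random.default_rng(0), 3, 4)
        for name in vars(w):
            getattr(w, name)[:] = 0.0
        out = lstm_cell_step(np.ones(3), LSTMState.zeros(4), w)
        np.testing.assert_array_equal(out.c, 0.0)
        np.testing.assert_array_equal(out.h, 0.0)

    def test_scalar_hand_evaluation(self):
        """1-unit cell with zero weights except a large candidate bias:
        gates sit at 0.5, candidate saturates, so c1 ~ 0.5 and
        h1 ~ 0.5 * tanh(0.5)."""
        w = random_weights(np.random.default_rng(0), 1, 1)
        for name in vars(w):
            getattr(w, name)[:] = 0.0
        w.b_c[:] = 50.0  # sigma_c ~ 1
        out = lstm_cell_step(np.zeros(1), LSTMState.zeros(1), w)
        assert out.c[0] == pytest.approx(0.5, abs=1e-9)
        assert out.h[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-9)

    def test_matches_naive_oracle_on_random_instances(self):
        """100 random small instances agree with the element-by-element
        restatement of the gate formulas to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_in = int(rng.integers(1, 5))
            units = int(rng.integers(1, 6))
            w = random_weights(rng, n_in, units)
            x = rng.normal(size=n_in)
            prev = LSTMState(rng.normal(size=units), rng.normal(size=units))
            got = lstm_cell_step(x, prev, w)
            c_ref, h_ref = naive_cell_step(x, prev.c, prev.h, w)
            np.testing.assert_allclose(got.c, c_ref, atol=1e-10)
            np.testing.assert_allclose(got.h, h_ref, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        w = random_weights(np.random.default_rng(0), 3, 4)
        with pytest.raises(ValueError):
            lstm_cell_step(np.ones(5), LSTMState.zeros(4), w)


class TestStackForward:
    def test_packed_stack_matches_reference_cell_path(self):
        """The vectorized stack equals the per-gate reference cell applied
        layer by layer, hour by hour."""
        cfg = ModelConfig(n_layers=3, units_per_layer=6, dropout_p=0.0,
                          seed=5)
        model = LSTMClassifier(4, cfg)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(7, 4))
        probs = model.forward(X)
        inp = X
        for layer in range(cfg.n_layers):
            w = model.layer_weights(layer)
            state = LSTMState.zeros(cfg.units_per_layer)
            hs = []
            for t in range(len(inp)):
                state = lstm_cell_step(inp[t], state, w)
                hs.append(state.h)
            inp = np.array(hs)
        logits = inp @ model.params["w_out"] + model.params["b_out"][0]
        np.testing.assert_allclose(probs, _sigmoid(logits), atol=1e-10)

    def test_zero_weight_stack_outputs_half(self):
        model = LSTMClassifier(3, ModelConfig(n_layers=2, units_per_layer=4))
        for k in model.params:
            model.params[k][:] = 0.0
        probs = model.forward(np.random.default_rng(0).normal(size=(6, 3)))
        np.testing.assert_allclose(probs, 0.5)

    def test_length_one_sequence(self):
        model = LSTMClassifier(3, ModelConfig(n_layers=1, units_per_layer=4))
        assert model.forward(np.zeros((1, 3))).shape == (1,)

    def test_feature_permutation_invariance(self):
        """Permuting feature order together with the first layer's W rows
        leaves the output unchanged."""
        model = LSTMClassifier(5, ModelConfig(n_layers=2, units_per_layer=4,
                                              seed=2))
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 5))
        p1 = model.forward(X)
        perm = rng.permutation(5)
        model.params["W0"] = model.params["W0"][perm]
        p2 = model.forward(X[:, perm])
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_causality_future_perturbation(self):
        model = LSTMClassifier(3, ModelConfig(n_layers=2, units_per_layer=8,
                                              seed=4))
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 3))
        X2 = X.copy()
        X2[8:] += 50.0
        np.testing.assert_array_equal(model.forward(X)[:8],
                                      model.forward(X2)[:8])

    def test_truncation_reproduces_prefix(self):
        model = LSTMClassifier(3, ModelConfig(n_layers=2, units_per_layer=8,
                                              seed=4))
        X = np.random.default_rng(6).normal(size=(10, 3))
        np.testing.assert_allclose(model.forward(X)[:4],
                                   model.forward(X[:4]), atol=1e-12)

    def test_hidden_states_bounded(self):
        """h is an output-gated tanh: every component lies in (-1, 1)."""
        cfg = ModelConfig(n_layers=2, units_per_layer=6, seed=7)
        model = LSTMClassifier(3, cfg)
        X = np.random.default_rng(8).normal(scale=10, size=(1, 20, 3))
        _, caches, top_h = model._forward(X, training=True,
                                          rng=np.random.default_rng(0))
        for cache in caches:
            assert np.all(np.abs(cache["hs"]) < 1.0)

    def test_non_dense_input_rejected(self):
        model = LSTMClassifier(3, ModelConfig(n_layers=1, units_per_layer=4))
        X = np.zeros((5, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValueError):
            model.forward(X)

    def test_feature_dimension_mismatch_rejected(self):
        model = LSTMClassifier(3, ModelConfig(n_layers=1, units_per_layer=4))
        with pytest.raises(ValueError):
            model.forward(np.zeros((5, 7)))


def _toy_sequences(n=40, T=12, seed=0):
    """Separable toy problem: positives drift upward over time."""
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n):
        label = i % 2 == 1
        X = rng.normal(0, 0.5, size=(T, 3))
        if label:
            X[:, 0] += np.linspace(0, 3, T)
        seqs.append(Sequence(f"t{i}", X, label))
    return seqs


class TestTraining:
    def test_loss_trend_non_increasing(self):
        seqs = _toy_sequences()
        cfg = ModelConfig(n_layers=1, units_per_layer=8, dropout_p=0.0,
                          epochs=12, batches_per_epoch=None, batch_size=8,
                          learning_rate=5e-3, val_interval=2, seed=1)
        model = LSTMClassifier(3, cfg)
        log = model.fit(seqs)
        losses = log["loss"].to_numpy()
        assert losses[-1] < losses[0]
        smoothed = np.convolve(losses, np.ones(3) / 3, mode="valid")
        assert smoothed[-1] <= smoothed[0]

    def test_learns_separable_signal(self):
        train = _toy_sequences(n=40, seed=0)
        test = _toy_sequences(n=20, seed=99)
        cfg = ModelConfig(n_layers=1, units_per_layer=8, dropout_p=0.0,
                          epochs=15, batches_per_epoch=None, batch_size=8,
                          learning_rate=5e-3, val_interval=5, seed=1)
        model = LSTMClassifier(3, cfg)
        model.fit(train)
        preds = model.predict(test)
        _, auroc = sw.roc_and_auroc([p.admission_score for p in preds],
                                    [s.label for s in test])
        assert auroc > 0.9

    def test_positive_weighting_raises_recall_at_matched_specificity(self):
        """On imbalanced data, positive weight 3 recalls at least as many
        positives as weight 1 when thresholds are set to the same
        specificity."""
        rng = np.random.default_rng(10)
        train = []
        for i in range(60):
            label = i < 10  # 1:5 imbalance
            X = rng.normal(0, 1.0, size=(10, 3))
            if label:
                X[:, 0] += np.linspace(0, 1.5, 10)
            train.append(Sequence(f"i{i}", X, label))
        test = []
        for i in range(60):
            label = i < 10
            X = rng.normal(0, 1.0, size=(10, 3))
            if label:
                X[:, 0] += np.linspace(0, 1.5, 10)
            test.append(Sequence(f"j{i}", X, label))

        recalls = {}
        for w in (1.0, 3.0):
            cfg = ModelConfig(n_layers=1, units_per_layer=8, dropout_p=0.0,
                              epochs=10, batches_per_epoch=None, batch_size=8,
                              learning_rate=5e-3, positive_weight=w,
                              val_interval=10, seed=2)
            model = LSTMClassifier(3, cfg)
            model.fit(train)
            scores = np.array([p.admission_score
                               for p in model.predict(test)])
            y = np.array([s.label for s in test])
            thr = np.quantile(scores[~y], 0.8)  # specificity 0.8
            recalls[w] = (scores[y] >= thr).mean()
        assert recalls[3.0] >= recalls[1.0]

    def test_single_class_training_set_rejected(self):
        seqs = [Sequence("a", np.zeros((4, 3)), True)] * 4
        model = LSTMClassifier(3, ModelConfig(n_layers=1, units_per_layer=4))
        with pytest.raises(ValueError, match="both classes"):
            model.fit(seqs)

    def test_training_log_schema_and_interval(self):
        seqs = _toy_sequences(n=16)
        cfg = ModelConfig(n_layers=1, units_per_layer=4, epochs=6,
                          batches_per_epoch=None, batch_size=8,
                          val_interval=2, dropout_p=0.0, seed=3)
        model = LSTMClassifier(3, cfg)
        log = model.fit(seqs, val=_toy_sequences(n=10, seed=5))
        assert list(log.columns) == ["epoch", "loss", "train_auroc",
                                     "val_auroc"]
        assert log["epoch"].tolist() == [2, 4, 6]
        assert log["val_auroc"].notna().all()


@pytest.fixture(scope="module")
def trained():
    cfg = ModelConfig(n_layers=1, units_per_layer=6, epochs=4,
                      batches_per_epoch=None, batch_size=8,
                      dropout_p=0.3, seed=4)
    model = LSTMClassifier(3, cfg)
    model.fit(_toy_sequences(n=16))
    return model


class TestPredict:

    def test_repeated_calls_identical(self, trained):
        seqs = _toy_sequences(n=6, seed=20)
        p1 = trained.predict(seqs)
        p2 = trained.predict(seqs)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.probs, b.probs)

    def test_batch_equals_per_admission(self, trained):
        seqs = _toy_sequences(n=9, seed=21)
        batched = trained.predict(seqs, batch_size=4)
        single = [trained.predict([s])[0] for s in seqs]
        for a, b in zip(batched, single):
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)

    def test_probabilities_in_unit_interval(self, trained):
        for p in trained.predict(_toy_sequences(n=5, seed=22)):
            assert np.all((p.probs >= 0) & (p.probs <= 1))


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        cfg = ModelConfig(n_layers=2, units_per_layer=5, seed=6)
        model = LSTMClassifier(4, cfg, feature_names=list("abcd"))
        model.save(tmp_path / "ckpt")
        loaded = LSTMClassifier.load(tmp_path / "ckpt")
        X = np.random.default_rng(7).normal(size=(8, 4))
        np.testing.assert_array_equal(model.forward(X), loaded.forward(X))
        assert loaded.feature_names == list("abcd")
        assert loaded.config == cfg


class TestFullScaleConfig:
    def test_default_config_constructs_and_steps(self):
        """The full-scale configuration (4 layers x 100 units, dropout 0.4,
        positive weight 3) builds and runs one forward/backward update."""
        cfg = ModelConfig()
        assert (cfg.n_layers, cfg.units_per_layer) == (4, 100)
        assert (cfg.dropout_p, cfg.epochs) == (0.4, 1000)
        assert (cfg.batches_per_epoch, cfg.batch_size) == (40, 50)
        assert cfg.positive_weight == 3.0
        model = LSTMClassifier(31, cfg)
        rng = np.random.default_rng(0)
        batch = [Sequence("p", rng.normal(size=(6, 31)), True),
                 Sequence("n", rng.normal(size=(9, 31)), False)]
        loss = model.train_step(batch, rng)
        assert np.isfinite(loss)

    def test_gate_packing_order(self):
        assert GATE_ORDER == ("i", "f", "c", "o")
        W = np.arange(8, dtype=float).reshape(2, 4)
        U = np.arange(4, dtype=float).reshape(1, 4)
        b = np.arange(4, dtype=float)
        w = LSTMCellWeights.from_packed(W, U, b)
        assert w.b_i[0] == 0 and w.b_f[0] == 1 and w.b_c[0] == 2 \
            and w.b_o[0] == 3
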