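"""LSTM cell algebra against a scalar-loop oracle; training/prediction behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from texhawk.lstm import (
    CellState,
    ClassifierConfig,
    LSTMCellParams,
    LSTMClassifier,
    lstm_cell_forward,
    predict,
    sequence_forward,
    train_classifier,
)
from texhawk.table import FeatureTable


def scalar_sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


def oracle_cell(x, h, c, params, paper_literal=False):
    """Pure-Python per-unit loop, independent of the vectorized implementation."""
    H, D = params.hidden_size, params.input_size
    h_new, c_new = [0.0] * H, [0.0] * H
    for u in range(H):
        acts = {}
        for gate in ("f", "i", "o", "c"):
            z = params.b[gate][u]
            for d in range(D):
                z += params.W[gate][u][d] * x[d]
            for v in range(H):
                z += params.U[gate][u][v] * h[v]
            acts[gate] = math.tanh(z) if gate == "c" else scalar_sigmoid(z)
        c_new[u] = acts["f"] * c[u] + acts["i"] * acts["c"]
        if paper_literal:
            h_new[u] = math.tanh(c_new[u]) + acts["o"]
        else:
            h_new[u] = acts["o"] * math.tanh(c_new[u])
    return np.array(h_new), np.array(c_new)


def random_params(rng, hidden, inp):
    return LSTMCellParams(
        W={g: rng.normal(size=(hidden, inp)) for g in ("f", "i", "o", "c")},
        U={g: rng.normal(size=(hidden, hidden)) for g in ("f", "i", "o", "c")},
        b={g: rng.normal(size=hidden) for g in ("f", "i", "o", "c")},
    )


class TestCellForward:
    def test_zero_params_zero_state(self):
        params = LSTMCellParams.zeros(3, 2)
        out = lstm_cell_forward(np.zeros(2), CellState.zeros(3), params)
        np.testing.assert_array_equal(out.h, 0.0)
        np.testing.assert_array_equal(out.c, 0.0)

    def test_zero_params_unit_memory_scalar(self):
        params = LSTMCellParams.zeros(1, 1)
        out = lstm_cell_forward(np.zeros(1), CellState(h=np.zeros(1), c=np.ones(1)), params)
        assert out.c[0] == pytest.approx(0.5)
        assert out.h[0] == pytest.approx(0.5 * math.tanh(0.5))

    def test_saturated_gates_carry_memory_exactly(self):
        params = LSTMCellParams.zeros(2, 1)
        params.b["f"][:] = 500.0  # forget gate pinned open
        params.b["i"][:] = -500.0  # input gate pinned shut
        c0 = np.array([0.7, -1.3])
        out = lstm_cell_forward(np.array([0.4]), CellState(h=np.zeros(2), c=c0), params)
        np.testing.assert_array_equal(out.c, c0)

    @pytest.mark.parametrize("paper_literal", [False, True])
    def test_matches_scalar_loop_oracle(self, paper_literal):
        rng = np.random.default_rng(8)
        for _ in range(30):
            H, D = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            params = random_params(rng, H, D)
            x, h, c = rng.normal(size=D), rng.normal(size=H), rng.normal(size=H)
            got = lstm_cell_forward(x, CellState(h=h, c=c), params, paper_literal)
            want_h, want_c = oracle_cell(x, h, c, params, paper_literal)
            np.testing.assert_allclose(got.h, want_h, atol=1e-10)
            np.testing.assert_allclose(got.c, want_c, atol=1e-10)

    def test_gate_ranges(self):
        rng = np.random.default_rng(9)
        params = random_params(rng, 4, 3)
        out = lstm_cell_forward(rng.normal(size=3) * 10, CellState.zeros(4), params)
        assert np.all(np.abs(out.h) < 1.0)  # |o * tanh(c)| < 1 always

    def test_dim_mismatch_rejected(self):
        params = LSTMCellParams.zeros(2, 3)
        with pytest.raises(ValueError):
            lstm_cell_forward(np.zeros(5), CellState.zeros(2), params)


class TestSequenceForward:
    def test_length_one_equals_single_cell(self):
        rng = np.random.default_rng(10)
        params = random_params(rng, 3, 2)
        x = rng.normal(size=(1, 2))
        a = sequence_forward(x, params)
        b = lstm_cell_forward(x[0], CellState.zeros(3), params)
        np.testing.assert_array_equal(a.h, b.h)

    def test_three_steps_equal_chained_calls(self):
        rng = np.random.default_rng(11)
        params = random_params(rng, 3, 2)
        seq = rng.normal(size=(3, 2))
        folded = sequence_forward(seq, params)
        state = CellState.zeros(3)
        for t in range(3):
            state = lstm_cell_forward(seq[t], state, params)
        np.testing.assert_allclose(folded.h, state.h, atol=1e-14)
        np.testing.assert_allclose(folded.c, state.c, atol=1e-14)

    def test_zero_everything_stays_zero(self):
        params = LSTMCellParams.zeros(2, 2)
        out = sequence_forward(np.zeros((4, 2)), params)
        np.testing.assert_array_equal(out.h, 0.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_forward(np.empty((0, 2)), LSTMCellParams.zeros(2, 2))


def separable_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 2)) * 0.3 + np.column_stack([2.0 * (y - 0.5), -2.0 * (y - 0.5)])
    return FeatureTable(X=pd.DataFrame(X, columns=["a", "b"]), y=y)


class TestTraining:
    def test_separable_fixture_learned(self):
        table = separable_table()
        model = train_classifier(table, ClassifierConfig(hidden_size=8, chunk_len=2, epochs=100, seed=0))
        labels, _ = predict(model, table.values())
        assert np.mean(labels == table.y) >= 0.95
        assert model.loss_history[-1] < model.loss_history[0]

    def test_shuffled_labels_chance_level(self):
        table = separable_table(seed=1)
        rng = np.random.default_rng(2)
        y_shuf = rng.permutation(table.y)
        half = len(y_shuf) // 2
        train = FeatureTable(X=table.X.iloc[:half], y=y_shuf[:half])
        model = train_classifier(train, ClassifierConfig(hidden_size=8, chunk_len=2, epochs=60, seed=0))
        labels, _ = predict(model, table.values()[half:])
        acc = np.mean(labels == y_shuf[half:])
        assert 0.3 <= acc <= 0.7

    def test_same_seed_identical_weights(self):
        table = separable_table(seed=3)
        cfg = ClassifierConfig(hidden_size=4, chunk_len=2, epochs=20, seed=5)
        m1 = train_classifier(table, cfg)
        m2 = train_classifier(table, cfg)
        for g in ("f", "i", "o", "c"):
            np.testing.assert_array_equal(m1.cell.W[g], m2.cell.W[g])
        np.testing.assert_array_equal(m1.w_out, m2.w_out)

    def test_single_class_rejected(self):
        t = separable_table()
        bad = FeatureTable(X=t.X, y=np.zeros(t.n_samples, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(bad)


class TestPredict:
    def test_probability_half_maps_to_positive(self):
        model = LSTMClassifier(ClassifierConfig(hidden_size=2, chunk_len=2, seed=0), n_features=2)
        model.w_out[:] = 0.0
        model.b_out = 0.0
        labels, proba = predict(model, np.array([[0.3, -0.2]]))
        assert proba[0] == pytest.approx(0.5)
        assert labels[0] == 1

    def test_batch_equals_per_sample(self):
        table = separable_table(seed=4)
        model = train_classifier(table, ClassifierConfig(hidden_size=4, chunk_len=2, epochs=10, seed=1))
        X = table.values()[:5]
        batch_labels, batch_proba = predict(model, X)
        for k in range(5):
            lab, pro = predict(model, X[k : k + 1])
            assert lab[0] == batch_labels[k]
            assert pro[0] == pytest.approx(batch_proba[k])

    def test_memorizes_tiny_training_set(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 4)) * 2
        y = np.array([0, 1] * 4)
        table = FeatureTable(X=pd.DataFrame(X, columns=list("wxyz")), y=y)
        model = train_classifier(table, ClassifierConfig(hidden_size=12, chunk_len=2, epochs=800, learning_rate=0.2, seed=0))
        labels, _ = predict(model, X)
        assert np.array_equal(labels, y)

    def test_dim_mismatch_rejected(self):
        model = LSTMClassifier(ClassifierConfig(hidden_size=2, chunk_len=2, seed=0), n_features=4)
        with pytest.raises(ValueError):
            predict(model, np.zeros((1, 3)))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        table = separable_table(seed=7)
        model = train_classifier(table, ClassifierConfig(hidden_size=4, chunk_len=2, epochs=15, seed=2))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = LSTMClassifier.load(path)
        np.testing.assert_allclose(
            model.predict_proba(table.values()), loaded.predict_proba(table.values()), atol=1e-15
        )


def test_paper_literal_output_rule():
    """The alternative read-out h = tanh(c) + o differs from the gated default."""
    rng = np.random.default_rng(12)
    params = random_params(rng, 3, 2)
    x = rng.normal(size=2)
    state = CellState(h=rng.normal(size=3), c=rng.normal(size=3))
    default = lstm_cell_forward(x, state, params, paper_literal=False)
    literal = lstm_cell_forward(x, state, params, paper_literal=True)
    np.testing.assert_array_equal(default.c, literal.c)
    assert not np.allclose(default.h, literal.h)
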