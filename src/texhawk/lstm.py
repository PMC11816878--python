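"""LSTM binary classifier over selected feature vectors.

The cell follows the standard gated recurrence

    f = sigmoid(W_f x + U_f h + b_f)        (forget gate)
    i = sigmoid(W_i x + U_i h + b_i)        (input gate)
    o = sigmoid(W_o x + U_o h + b_o)        (output gate)
    g = tanh(W_c x + U_c h + b_c)           (candidate memory)
    c' = f * c + i * g
    h' = o * tanh(c')

with an affine + sigmoid read-out on the final hidden state.  A
``paper_literal`` switch replaces the output rule with h' = tanh(c') + o, an
alternative (non-gated) combination kept for comparison runs.

Flat feature vectors are presented as a sequence of fixed-length chunks
(zero-padded), so a 40-feature vector with chunk length 8 becomes 5 time
steps.  Training is plain mini-batch gradient descent on binary cross-entropy
with gradients from backpropagation through time; everything is numpy and
fully deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .table import FeatureTable

__all__ = [
    "LSTMCellParams",
    "CellState",
    "ClassifierConfig",
    "lstm_cell_forward",
    "sequence_forward",
    "LSTMClassifier",
    "train_classifier",
    "predict",
]

_GATES = ("f", "i", "o", "c")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMCellParams:
    """Gate weights: W_* act on the input, U_* on the previous hidden state."""

    W: dict[str, np.ndarray]
    U: dict[str, np.ndarray]
    b: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.W) != set(_GATES) or set(self.U) != set(_GATES) or set(self.b) != set(_GATES):
            raise ValueError(f"expected weight entries for gates {_GATES}")
        H, D = self.W["f"].shape
        for g in _GATES:
            if self.W[g].shape != (H, D) or self.U[g].shape != (H, H) or self.b[g].shape != (H,):
                raise ValueError(f"inconsistent shapes for gate {g!r}")
            for arr in (self.W[g], self.U[g], self.b[g]):
                if not np.all(np.isfinite(arr)):
                    raise ValueError("cell parameters must be finite")

    @property
    def hidden_size(self) -> int:
        return self.W["f"].shape[0]

    @property
    def input_size(self) -> int:
        return self.W["f"].shape[1]

    @classmethod
    def zeros(cls, hidden_size: int, input_size: int) -> "LSTMCellParams":
        return cls(
            W={g: np.zeros((hidden_size, input_size)) for g in _GATES},
            U={g: np.zeros((hidden_size, hidden_size)) for g in _GATES},
            b={g: np.zeros(hidden_size) for g in _GATES},
        )

    @classmethod
    def init_random(cls, hidden_size: int, input_size: int, rng: np.random.Generator) -> "LSTMCellParams":
        def w(shape):
            return rng.standard_normal(shape) / np.sqrt(shape[-1])

        b = {g: np.zeros(hidden_size) for g in _GATES}
        b["f"] = np.ones(hidden_size)  # open forget gate at init, the usual trick
        return cls(
            W={g: w((hidden_size, input_size)) for g in _GATES},
            U={g: w((hidden_size, hidden_size)) for g in _GATES},
            b=b,
        )


@dataclass
class CellState:
    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, hidden_size: int, batch: int | None = None) -> "CellState":
        shape = (hidden_size,) if batch is None else (batch, hidden_size)
        return cls(h=np.zeros(shape), c=np.zeros(shape))


def lstm_cell_forward(
    x: np.ndarray,
    state: CellState,
    params: LSTMCellParams,
    paper_literal: bool = False,
) -> CellState:
    """One gated update; ``x`` may be a vector or a (batch, input) matrix."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != params.input_size:
        raise ValueError(f"input size {x.shape[-1]} != expected {params.input_size}")
    if state.h.shape != state.c.shape or state.h.shape[-1] != params.hidden_size:
        raise ValueError("state dims inconsistent with hidden_size")
    pre = {g: x @ params.W[g].T + state.h @ params.U[g].T + params.b[g] for g in _GATES}
    f = _sigmoid(pre["f"])
    i = _sigmoid(pre["i"])
    o = _sigmoid(pre["o"])
    g = np.tanh(pre["c"])
    c_new = f * state.c + i * g
    h_new = np.tanh(c_new) + o if paper_literal else o * np.tanh(c_new)
    return CellState(h=h_new, c=c_new)


def sequence_forward(
    sequence: np.ndarray,
    params: LSTMCellParams,
    initial: CellState | None = None,
    paper_literal: bool = False,
) -> CellState:
    """Left fold of the cell over time steps; axis 0 of ``sequence`` is time."""
    seq = np.asarray(sequence, dtype=np.float64)
    if seq.shape[0] == 0:
        raise ValueError("sequence must be non-empty")
    batch = seq.shape[1] if seq.ndim == 3 else None
    state = initial or CellState.zeros(params.hidden_size, batch)
    for t in range(seq.shape[0]):
        state = lstm_cell_forward(seq[t], state, params, paper_literal)
    return state


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_size: int = 16
    chunk_len: int = 8
    epochs: int = 200
    learning_rate: float = 0.05
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.chunk_len < 1:
            raise ValueError("hidden_size and chunk_len must be positive")
        if self.epochs < 1 or self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("epochs, learning_rate and batch_size must be positive")


def _to_sequences(X: np.ndarray, chunk_len: int) -> np.ndarray:
    """(n, d) -> (T, n, chunk_len): zero-pad d up to a chunk multiple, then chunk."""
    n, d = X.shape
    T = -(-d // chunk_len)
    padded = np.zeros((n, T * chunk_len))
    padded[:, :d] = X
    return padded.reshape(n, T, chunk_len).transpose(1, 0, 2)


class LSTMClassifier:
    """Single-layer LSTM + affine/sigmoid read-out trained with BPTT."""

    FORMAT_VERSION = 1

    def __init__(self, config: ClassifierConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        self.cell = LSTMCellParams.init_random(config.hidden_size, config.chunk_len, rng)
        self.w_out = rng.standard_normal(config.hidden_size) / np.sqrt(config.hidden_size)
        self.b_out = 0.0
        self.loss_history: list[float] = []

    # -- forward ----------------------------------------------------------

    def _forward_cached(self, seq: np.ndarray):
        """Forward over a (T, batch, d) sequence, caching per-step activations."""
        T, n, _ = seq.shape
        H = self.config.hidden_size
        state = CellState.zeros(H, n)
        cache = []
        for t in range(T):
            x = seq[t]
            pre = {g: x @ self.cell.W[g].T + state.h @ self.cell.U[g].T + self.cell.b[g] for g in _GATES}
            f, i, o = _sigmoid(pre["f"]), _sigmoid(pre["i"]), _sigmoid(pre["o"])
            g = np.tanh(pre["c"])
            c_new = f * state.c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((x, state.h, state.c, f, i, o, g, c_new))
            state = CellState(h=h_new, c=c_new)
        return state, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        seq = _to_sequences(X, self.config.chunk_len)
        state = sequence_forward(seq, self.cell)
        return _sigmoid(state.h @ self.w_out + self.b_out)

    # -- training ---------------------------------------------------------

    def _batch_gradients(self, seq: np.ndarray, y: np.ndarray):
        state, cache = self._forward_cached(seq)
        n = y.size
        p = _sigmoid(state.h @ self.w_out + self.b_out)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dz = (p - y) / n
        grads = {
            "W": {g: np.zeros_like(self.cell.W[g]) for g in _GATES},
            "U": {g: np.zeros_like(self.cell.U[g]) for g in _GATES},
            "b": {g: np.zeros_like(self.cell.b[g]) for g in _GATES},
            "w_out": state.h.T @ dz,
            "b_out": float(dz.sum()),
        }
        dh = np.outer(dz, self.w_out)
        dc = np.zeros_like(dh)
        for t in range(len(cache) - 1, -1, -1):
            x, h_prev, c_prev, f, i, o, g, c_new = cache[t]
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            df, di, dg = dc * c_prev, dc * g, dc * i
            da = {
                "f": df * f * (1 - f),
                "i": di * i * (1 - i),
                "o": do * o * (1 - o),
                "c": dg * (1 - g * g),
            }
            dh = np.zeros_like(h_prev)
            for gate in _GATES:
                grads["W"][gate] += da[gate].T @ x
                grads["U"][gate] += da[gate].T @ h_prev
                grads["b"][gate] += da[gate].sum(axis=0)
                dh += da[gate] @ self.cell.U[gate]
            dc = dc * f
        return loss, grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_features) matching y")
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        rng = np.random.default_rng(self.config.seed + 1)
        lr = self.config.learning_rate
        n = X.shape[0]
        for _ in range(self.config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.config.batch_size):
                idx = order[start : start + self.config.batch_size]
                seq = _to_sequences(X[idx], self.config.chunk_len)
                loss, grads = self._batch_gradients(seq, y[idx])
                epoch_loss += loss * idx.size
                for gate in _GATES:
                    self.cell.W[gate] -= lr * grads["W"][gate]
                    self.cell.U[gate] -= lr * grads["U"][gate]
                    self.cell.b[gate] -= lr * grads["b"][gate]
                self.w_out -= lr * grads["w_out"]
                self.b_out -= lr * grads["b_out"]
            self.loss_history.append(epoch_loss / n)
        return self

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        blob = {
            "format_version": self.FORMAT_VERSION,
            "config": self.config.__dict__,
            "n_features": self.n_features,
            "W": {g: self.cell.W[g].tolist() for g in _GATES},
            "U": {g: self.cell.U[g].tolist() for g in _GATES},
            "b": {g: self.cell.b[g].tolist() for g in _GATES},
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "LSTMClassifier":
        blob = json.loads(Path(path).read_text())
        if blob.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format {blob.get('format_version')}")
        model = cls(ClassifierConfig(**blob["config"]), blob["n_features"])
        model.cell = LSTMCellParams(
            W={g: np.asarray(blob["W"][g]) for g in _GATES},
            U={g: np.asarray(blob["U"][g]) for g in _GATES},
            b={g: np.asarray(blob["b"][g]) for g in _GATES},
        )
        model.w_out = np.asarray(blob["w_out"])
        model.b_out = float(blob["b_out"])
        return model


def train_classifier(table: FeatureTable, config: ClassifierConfig | None = None) -> LSTMClassifier:
    """Train the LSTM on a (already standardized, mask-restricted) feature table."""
    import logging

    config = config or ClassifierConfig()
    if len(np.unique(table.y)) < 2:
        raise ValueError("training requires both classes present")
    X = table.values()
    if np.any(X.std(axis=0) == 0):
        logging.getLogger(__name__).warning("constant feature column(s) present; training proceeds")
    return LSTMClassifier(config, table.n_features).fit(X, table.y)


def predict(model: LSTMClassifier, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and 0/1 labels (label 1 iff probability >= 0.5)."""
    proba = model.predict_proba(features)
    return (proba >= 0.5).astype(np.int64), proba
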