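"""Wrapper feature selection: hawk positions -> binary masks -> error+sparsity cost.

Each continuous hawk position in [0, 1]^n is thresholded into a feature mask;
the mask is scored by

    cost = w1 * Error(mask) + w2 * m / n

where Error is the cross-validated misclassification rate of a small
multilayer perceptron trained on the masked columns, m the number of selected
features
and n the total.  The error term keeps selection supervised; the m/n term
rewards dimensionality reduction.  Costs are cached by mask bits because the
optimizer revisits subsets often.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .hho import ConvergenceHistory, HHOParams, HHOResult, hho_minimize
from .table import FeatureTable

__all__ = [
    "FeatureMask",
    "SelectionCostWeights",
    "EvaluatorConfig",
    "binarize",
    "evaluator_error",
    "selection_cost",
    "hho_select_features",
]


@dataclass(frozen=True)
class FeatureMask:
    """Binary indicator over features; ``m`` of ``n`` selected."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.bits or any(b not in (0, 1) for b in self.bits):
            raise ValueError("mask bits must be a non-empty 0/1 vector")

    @property
    def m(self) -> int:
        return int(sum(self.bits))

    @property
    def n(self) -> int:
        return len(self.bits)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=np.int64)

    def selected_names(self, names: list[str]) -> list[str]:
        return [nm for nm, b in zip(names, self.bits) if b]


@dataclass(frozen=True)
class SelectionCostWeights:
    """Error weight w1 and sparsity weight w2, normalized to w1 + w2 = 1.

    The conventional wrapper-selection setting keeps error dominant
    (w1 = 0.99, w2 = 0.01)."""

    w1: float = 0.99
    w2: float = 0.01

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 == 0:
            raise ValueError("weights must be non-negative and not both zero")
        total = self.w1 + self.w2
        object.__setattr__(self, "w1", self.w1 / total)
        object.__setattr__(self, "w2", self.w2 / total)


@dataclass(frozen=True)
class EvaluatorConfig:
    """Settings of the subset-scoring multilayer perceptron.

    ``n_folds >= 2`` scores a mask by stratified k-fold cross-validated error
    (the default: every sample is validated once, which gives the cost finer
    resolution than a single holdout and resists split-specific overfitting);
    ``n_folds = 1`` uses a single stratified holdout of ``holdout_fraction``.
    ``n_repeats`` averages the k-fold error over that many distinct fold
    partitions (all derived from ``seed``), which damps the selection-time
    overfitting that thousands of mask evaluations against one fixed
    partition would otherwise reward.
    """

    hidden_sizes: tuple[int, ...] = (16,)
    epochs: int = 50
    learning_rate: float = 0.01
    solver: str = "adam"
    n_folds: int = 5
    n_repeats: int = 2
    holdout_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes) or not self.hidden_sizes:
            raise ValueError("hidden_sizes must be positive")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1 (1 = single holdout)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs and learning_rate must be positive")
        if self.solver not in ("lbfgs", "adam", "sgd"):
            raise ValueError(f"unknown solver {self.solver!r}")


def binarize(position: np.ndarray, threshold: float = 0.5) -> FeatureMask:
    """Threshold a continuous position into a mask (bit set iff coord >= threshold).

    An all-zero result is repaired by setting the largest coordinate's bit, so
    every evaluated mask selects at least one feature.
    """
    pos = np.asarray(position, dtype=np.float64)
    bits = (pos >= threshold).astype(np.int64)
    if bits.sum() == 0:
        bits[int(np.argmax(pos))] = 1
    return FeatureMask(bits=tuple(int(b) for b in bits))


def _fit_predict_errors(X_tr, y_tr, X_va, y_va, evaluator: EvaluatorConfig) -> int:
    scaler = StandardScaler().fit(X_tr)
    clf = MLPClassifier(
        hidden_layer_sizes=evaluator.hidden_sizes,
        max_iter=evaluator.epochs,
        learning_rate_init=evaluator.learning_rate,
        solver=evaluator.solver,
        random_state=evaluator.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(scaler.transform(X_tr), y_tr)
    return int(np.sum(clf.predict(scaler.transform(X_va)) != y_va))


def evaluator_error(mask: FeatureMask, table: FeatureTable, evaluator: EvaluatorConfig) -> float:
    """Validation misclassification rate of the evaluator MLP on masked columns.

    Deterministic under (mask, table, evaluator.seed): the internal stratified
    split(s) and the network initialization both derive from the config seed.
    """
    if mask.m < 1:
        raise ValueError("cannot evaluate an empty mask; repair upstream")
    if mask.n != table.n_features:
        raise ValueError(f"mask over {mask.n} features but table has {table.n_features}")
    if len(np.unique(table.y)) < 2:
        raise ValueError("evaluator requires both classes present")
    X = table.values()[:, mask.as_array().astype(bool)]
    y = table.y
    if evaluator.n_folds == 1:
        X_tr, X_va, y_tr, y_va = train_test_split(
            X, y, test_size=evaluator.holdout_fraction, random_state=evaluator.seed, stratify=y
        )
        return _fit_predict_errors(X_tr, y_tr, X_va, y_va, evaluator) / y_va.size
    n_wrong = 0
    for rep in range(evaluator.n_repeats):
        folds = StratifiedKFold(
            n_splits=evaluator.n_folds, shuffle=True, random_state=evaluator.seed + 1000 * rep
        )
        n_wrong += sum(
            _fit_predict_errors(X[tr], y[tr], X[va], y[va], evaluator) for tr, va in folds.split(X, y)
        )
    return n_wrong / (y.size * evaluator.n_repeats)


def selection_cost(
    mask: FeatureMask,
    table: FeatureTable,
    weights: SelectionCostWeights | None = None,
    evaluator: EvaluatorConfig | None = None,
    _cache: dict | None = None,
) -> float:
    """Weighted error-plus-sparsity cost of one feature mask."""
    weights = weights or SelectionCostWeights()
    evaluator = evaluator or EvaluatorConfig()
    if _cache is not None and mask.bits in _cache:
        return _cache[mask.bits]
    err = evaluator_error(mask, table, evaluator) if weights.w1 > 0 else 0.0
    cost = weights.w1 * err + weights.w2 * (mask.m / mask.n)
    if _cache is not None:
        _cache[mask.bits] = cost
    return cost


def hho_select_features(
    table: FeatureTable,
    hho: HHOParams | None = None,
    weights: SelectionCostWeights | None = None,
    evaluator: EvaluatorConfig | None = None,
    threshold: float = 0.5,
) -> tuple[FeatureMask, ConvergenceHistory]:
    """Run the hawks over [0, 1]^n_features and return the best mask ever scored."""
    hho = hho or HHOParams()
    if (np.asarray(hho.lb) != 0).any() or (np.asarray(hho.ub) != 1).any():
        hho = HHOParams(
            n_hawks=hho.n_hawks,
            n_iter=hho.n_iter,
            lb=0.0,
            ub=1.0,
            e0_fixed=hho.e0_fixed,
            levy_dives=hho.levy_dives,
            seed=hho.seed,
        )
    weights = weights or SelectionCostWeights()
    evaluator = evaluator or EvaluatorConfig()
    cache: dict[tuple[int, ...], float] = {}
    best: dict = {"mask": None, "cost": np.inf}

    def objective(x: np.ndarray) -> float:
        mask = binarize(x, threshold)
        cost = selection_cost(mask, table, weights, evaluator, _cache=cache)
        if cost < best["cost"]:
            best["mask"], best["cost"] = mask, cost
        return cost

    result = hho_minimize(objective, dim=table.n_features, params=hho)
    return best["mask"], result.history
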