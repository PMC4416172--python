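"""Weighted decision-tree base classifier shared by the MIL and SIL paths.

The base learner is a CART decision tree fitted with per-instance sample
weights.  Class probabilities are read off the leaf a sample falls into,
with add-one (Laplace) smoothing of the leaf's weighted class counts so
that probabilities never reach exactly 0 or 1 — this stabilises bag-level
averaging and avoids massive AUC ties from pure leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import TrainingError

__all__ = ["TreeConfig", "fit_weighted_tree", "positive_probability"]


@dataclass(frozen=True)
class TreeConfig:
    """Controls for the decision-tree base classifier.

    ``min_samples_leaf`` defaults to 20 so leaves aggregate roughly a
    bag's worth of instances instead of memorising single windows — a
    stand-in for the pruning a classic C4.5 tree would apply.  ``seed``
    fixes stochastic tie-breaking among equally good splits.
    """

    max_depth: Optional[int] = None
    min_samples_leaf: int = 20
    criterion: str = "entropy"
    seed: int = 0
    laplace: float = 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TreeConfig":
        return cls(**d)


def fit_weighted_tree(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: Optional[np.ndarray],
    config: TreeConfig,
) -> DecisionTreeClassifier:
    """Fit the base tree; both classes (0 and 1) must be present."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TrainingError("training data contains a single class; need positives and negatives")
    est = DecisionTreeClassifier(
        criterion=config.criterion,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        random_state=config.seed,
    )
    est.fit(np.asarray(X, dtype=float), y, sample_weight=sample_weight)
    return est


_VALUE_IS_NORMALIZED: Optional[bool] = None


def _value_is_normalized() -> bool:
    """Whether this scikit-learn stores per-node class *fractions* in tree_.value.

    Older releases stored weighted counts; probe once with a tree whose
    root counts are known.
    """
    global _VALUE_IS_NORMALIZED
    if _VALUE_IS_NORMALIZED is None:
        probe = DecisionTreeClassifier(max_depth=1, random_state=0)
        probe.fit([[0.0], [0.0], [1.0]], [0, 0, 1])
        root = probe.tree_.value[0, 0]
        _VALUE_IS_NORMALIZED = bool(abs(float(root.sum()) - 1.0) < 1e-9)
    return _VALUE_IS_NORMALIZED


def positive_probability(est, X: np.ndarray, *, laplace: float = 1.0) -> np.ndarray:
    """Positive-class probability per row.

    For a fitted decision tree, reads the leaf's weighted class counts and
    applies add-``laplace`` smoothing: p = (w_pos + a) / (w_total + 2a).
    Any other estimator with ``predict_proba`` is used as-is (hook for
    tests that plug in a memorising classifier).
    """
    X = np.asarray(X, dtype=float)
    if not isinstance(est, DecisionTreeClassifier):
        proba = est.predict_proba(X)
        classes = list(getattr(est, "classes_", [0, 1]))
        return np.asarray(proba)[:, classes.index(1)]
    leaves = est.apply(X)
    value = est.tree_.value[leaves, 0, :]
    if _value_is_normalized():
        counts = value * est.tree_.weighted_n_node_samples[leaves][:, None]
    else:
        counts = value
    pos_col = int(np.flatnonzero(est.classes_ == 1)[0])
    if laplace <= 0:
        total = counts.sum(axis=1)
        return counts[:, pos_col] / np.where(total > 0, total, 1.0)
    return (counts[:, pos_col] + laplace) / (counts.sum(axis=1) + 2.0 * laplace)
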