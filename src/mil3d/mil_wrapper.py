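"""The wrapper multiple-instance learner.

The wrapper approach converts a MIL problem into an ordinary weighted
single-instance problem: every instance inherits its bag's label and an
initial weight of 1/(bag size), a standard probabilistic classifier is
fitted on the flattened rows, and a bag is scored by the unweighted
arithmetic mean of its instances' positive-class probabilities.  Because
any single-instance classifier can serve as the base learner, MIL and SIL
models built on the same base classifier are directly comparable.

Instance-level probabilities are also exposed: within high-scoring
(positive) bags, the highest-probability windows are the model's candidate
binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np

from ._tree import TreeConfig, fit_weighted_tree, positive_probability
from .bags import Bag
from .errors import ConsistencyError, TrainingError
from .feature_tables import StructuralFeatureTable

__all__ = [
    "TreeConfig",
    "FlattenedTrainingSet",
    "TrainedModel",
    "BagPrediction",
    "flatten",
    "train",
    "predict_bag",
    "predict_bags",
    "instance_scores",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1


@dataclass
class FlattenedTrainingSet:
    """Bags flattened to weighted, bag-labelled single instances."""

    X: np.ndarray  # (n_rows, n_features)
    y: np.ndarray  # (n_rows,) 0/1
    weights: np.ndarray  # (n_rows,), sums to 1 within each bag
    provenance: List[Tuple[str, int]]  # row -> (probe_id, offset)
    bag_index: np.ndarray  # (n_rows,) index of the source bag


@dataclass
class TrainedModel:
    """A fitted base classifier plus the metadata needed to apply it."""

    base_classifier: object
    feature_model: str  # mil3d_kmer | sil3d | kmer_counting | combined_counting
    k: Optional[int]
    classifier_config: TreeConfig
    table_source: str = ""
    n_features: Optional[int] = None
    table: Optional[StructuralFeatureTable] = None

    def instance_probabilities(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.n_features is not None and X.shape[1] != self.n_features:
            raise ConsistencyError(
                f"feature length {X.shape[1]} does not match the model's {self.n_features}"
            )
        return positive_probability(self.base_classifier, X, laplace=self.classifier_config.laplace)


@dataclass
class BagPrediction:
    """Bag-level score with the per-instance probabilities behind it."""

    probe_id: str
    bag_probability: float
    instance_probabilities: List[float]


def flatten(bags: Sequence[Bag]) -> FlattenedTrainingSet:
    """One weighted row per instance, labelled with its bag's label.

    Raises
    ------
    ConsistencyError
        Empty input, or bags with differing k / feature lengths.
    """
    if not bags:
        raise ConsistencyError("no bags to flatten")
    k0, d0 = bags[0].k, bags[0].feature_length
    rows, labels, weights, provenance, bag_index = [], [], [], [], []
    for b_i, bag in enumerate(bags):
        if bag.k != k0 or bag.feature_length != d0:
            raise ConsistencyError(
                f"bag {bag.probe_id!r} has (k={bag.k}, d={bag.feature_length}), expected (k={k0}, d={d0})"
            )
        y = 1 if bag.label == "positive" else 0
        for inst in bag.instances:
            rows.append(inst.features)
            labels.append(y)
            weights.append(inst.weight)
            provenance.append((bag.probe_id, inst.offset))
            bag_index.append(b_i)
    return FlattenedTrainingSet(
        X=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=int),
        weights=np.asarray(weights, dtype=float),
        provenance=provenance,
        bag_index=np.asarray(bag_index, dtype=int),
    )


def _renormalise_per_bag(weights: np.ndarray, bag_index: np.ndarray) -> np.ndarray:
    totals = np.bincount(bag_index, weights=weights)
    return weights / totals[bag_index]


def train(
    bags: Sequence[Bag],
    config: TreeConfig | None = None,
    *,
    table_source: str = "",
    table: Optional[StructuralFeatureTable] = None,
    iterative_reweighting: bool = False,
    n_reweight_iterations: int = 2,
) -> TrainedModel:
    """Fit the wrapper MIL model on labelled bags.

    ``iterative_reweighting`` is an experimental, off-by-default variant:
    after the initial fit, instance weights are set proportional to the
    model's own instance probabilities (their complement within negative
    bags), renormalised per bag, and the tree is refitted for a fixed
    number of iterations.  The default single-pass fit is the reference
    behaviour.
    """
    config = config or TreeConfig()
    flat = flatten(bags)
    if flat.y.min() == flat.y.max():
        raise TrainingError("need at least one positive and one negative bag")
    est = fit_weighted_tree(flat.X, flat.y, flat.weights, config)
    if iterative_reweighting:
        for _ in range(n_reweight_iterations):
            p = positive_probability(est, flat.X, laplace=config.laplace)
            raw = np.where(flat.y == 1, p, 1.0 - p)
            raw = np.maximum(raw, 1e-6)
            w = _renormalise_per_bag(raw, flat.bag_index)
            est = fit_weighted_tree(flat.X, flat.y, w, config)
    return TrainedModel(
        base_classifier=est,
        feature_model="mil3d_kmer",
        k=bags[0].k,
        classifier_config=config,
        table_source=table_source or (table.source_name if table is not None else ""),
        n_features=bags[0].feature_length,
        table=table,
    )


def predict_bag(model: TrainedModel, bag: Bag) -> BagPrediction:
    """Score one bag: instance probabilities and their arithmetic mean.

    The bag probability is the *unweighted* mean of the positive-class
    probabilities of its instances.
    """
    probs = model.instance_probabilities(bag.feature_matrix())
    return BagPrediction(
        probe_id=bag.probe_id,
        bag_probability=float(np.mean(probs)),
        instance_probabilities=[float(p) for p in probs],
    )


def predict_bags(model: TrainedModel, bags: Sequence[Bag]) -> List[BagPrediction]:
    """Score many bags in one classifier pass (same result as per-bag calls)."""
    if not bags:
        return []
    sizes = [len(b.instances) for b in bags]
    X = np.concatenate([b.feature_matrix() for b in bags], axis=0)
    probs = model.instance_probabilities(X)
    out: List[BagPrediction] = []
    start = 0
    for bag, n in zip(bags, sizes):
        p = probs[start : start + n]
        start += n
        out.append(
            BagPrediction(
                probe_id=bag.probe_id,
                bag_probability=float(np.mean(p)),
                instance_probabilities=[float(v) for v in p],
            )
        )
    return out


def instance_scores(
    model: TrainedModel, bags: Sequence[Bag]
) -> List[Tuple[str, int, str, float]]:
    """Flat instance-level scores ``(probe_id, offset, kmer, probability)``.

    Sorted by probability descending, ties by (probe_id, offset).  Applied
    to positive bags this ranks candidate binding-site windows.
    """
    if not bags:
        return []
    preds = predict_bags(model, bags)
    scored = [
        (bag.probe_id, inst.offset, inst.kmer, prob)
        for bag, pred in zip(bags, preds)
        for inst, prob in zip(bag.instances, pred.instance_probabilities)
    ]
    scored.sort(key=lambda r: (-r[3], r[0], r[1]))
    return scored


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model (versioned joblib archive)."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "base_classifier": model.base_classifier,
        "feature_model": model.feature_model,
        "k": model.k,
        "classifier_config": model.classifier_config.to_dict(),
        "table_source": model.table_source,
        "n_features": model.n_features,
        "table_values": None if model.table is None else np.asarray(model.table.values),
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ConsistencyError(f"unsupported model format version {version!r}")
    table = None
    if payload.get("table_values") is not None:
        table = StructuralFeatureTable(values=payload["table_values"], source_name=payload.get("table_source", ""))
    return TrainedModel(
        base_classifier=payload["base_classifier"],
        feature_model=payload["feature_model"],
        k=payload["k"],
        classifier_config=TreeConfig.from_dict(payload["classifier_config"]),
        table_source=payload.get("table_source", ""),
        n_features=payload.get("n_features"),
        table=table,
    )
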