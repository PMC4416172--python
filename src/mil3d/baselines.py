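"""Single-instance baseline feature models.

Three comparison models share the MIL model's base classifier but describe
each probe with a single feature vector:

* **SIL3D** — positional concatenation of the structural parameters of
  every overlapping triplet of the probe, length (L-2)*6 (198 for L = 35).
  Position-sensitive by construction.
* **k-mer counting** — occurrence counts of all 4^k words of length k
  (overlapping, forward strand), the classic sequence-composition model.
* **3+4+5-mer counting** — the 3-, 4- and 5-mer count vectors concatenated,
  length 64 + 256 + 1024 = 1344.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from ._tree import TreeConfig, fit_weighted_tree
from .data_io import LabeledProbeSet
from .errors import ConsistencyError
from .feature_tables import StructuralFeatureTable, encode_sequence, kmer_structural_vector
from .mil_wrapper import TrainedModel

__all__ = [
    "FeatureModelSpec",
    "parse_model_spec",
    "sil3d_features",
    "kmer_count_features",
    "combined_count_features",
    "probe_feature_matrix",
    "train_sil",
    "predict_sil",
]


@dataclass(frozen=True)
class FeatureModelSpec:
    """A named feature model with its k-mer kernel length."""

    name: str  # mil3d_kmer | sil3d | kmer_counting | combined_counting
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.name not in ("mil3d_kmer", "sil3d", "kmer_counting", "combined_counting"):
            raise ValueError(f"unknown feature model {self.name!r}")
        if self.name in ("mil3d_kmer", "kmer_counting") and self.k is None:
            raise ValueError(f"feature model {self.name!r} requires k")

    @property
    def label(self) -> str:
        if self.name == "mil3d_kmer":
            return f"mil3d_k{self.k}"
        if self.name == "kmer_counting":
            return f"count_{self.k}"
        return {"sil3d": "sil3d", "combined_counting": "count345"}[self.name]

    def feature_length(self, probe_length: int = 35) -> int:
        if self.name == "mil3d_kmer":
            return (self.k - 2) * 6
        if self.name == "sil3d":
            return (probe_length - 2) * 6
        if self.name == "kmer_counting":
            return 4 ** self.k
        return 64 + 256 + 1024


def parse_model_spec(text: str, default_k: int = 7) -> FeatureModelSpec:
    """Parse model labels like ``mil3d_k7``, ``sil3d``, ``count_5``, ``count345``."""
    t = text.strip().lower()
    if t in ("sil3d",):
        return FeatureModelSpec("sil3d", 3)
    if t in ("count345", "combined", "combined_counting", "3+4+5mer_counting"):
        return FeatureModelSpec("combined_counting")
    if t.startswith("mil3d"):
        rest = t[len("mil3d") :].lstrip("_").lstrip("k").lstrip("_")
        k = int(rest) if rest else default_k
        return FeatureModelSpec("mil3d_kmer", k)
    if t.startswith("count"):
        rest = t[len("count") :].lstrip("_")
        k = int(rest) if rest else 5
        return FeatureModelSpec("kmer_counting", k)
    raise ValueError(f"cannot parse feature model {text!r}")


def sil3d_features(sequence: str, table: StructuralFeatureTable) -> np.ndarray:
    """Positional structural vector of a whole sequence, length (L-2)*6.

    Identical to the structural vector of the sequence treated as a single
    k-mer with k = L.
    """
    return kmer_structural_vector(sequence, table)


def kmer_count_features(sequence: str, k: int) -> np.ndarray:
    """Counts of all 4^k k-mers (overlapping, forward strand).

    Indexed by lexicographic k-mer order with A < C < G < T; the entries
    sum to L - k + 1.
    """
    if not 1 <= k <= 12:
        raise ValueError(f"k must be in [1, 12], got {k}")
    codes = encode_sequence(sequence)
    L = codes.size
    if L < k:
        raise ValueError(f"sequence length {L} is shorter than k = {k}")
    n = L - k + 1
    ranks = np.zeros(n, dtype=np.int64)
    for i in range(k):
        ranks = ranks * 4 + codes[i : n + i]
    return np.bincount(ranks, minlength=4 ** k).astype(np.int64)


def combined_count_features(sequence: str) -> np.ndarray:
    """3-, 4- and 5-mer count vectors concatenated (length 1344)."""
    if len(sequence) < 5:
        raise ValueError(f"sequence length {len(sequence)} is shorter than 5")
    return np.concatenate([kmer_count_features(sequence, k) for k in (3, 4, 5)])


def probe_feature_matrix(
    sequences: Sequence[str],
    spec: FeatureModelSpec,
    table: Optional[StructuralFeatureTable] = None,
) -> np.ndarray:
    """One feature row per probe sequence for a single-instance model."""
    if spec.name == "sil3d":
        if table is None:
            raise ValueError("sil3d features require a structural table")
        return np.stack([sil3d_features(s, table) for s in sequences])
    if spec.name == "kmer_counting":
        return np.stack([kmer_count_features(s, spec.k) for s in sequences]).astype(float)
    if spec.name == "combined_counting":
        return np.stack([combined_count_features(s) for s in sequences]).astype(float)
    raise ValueError(f"{spec.name!r} is not a single-instance feature model")


def features_and_labels(
    labeled: LabeledProbeSet,
    spec: FeatureModelSpec,
    table: Optional[StructuralFeatureTable] = None,
) -> tuple[np.ndarray, np.ndarray]:
    seqs = [p.sequence for p in labeled.positives] + [p.sequence for p in labeled.negatives]
    y = np.r_[np.ones(len(labeled.positives), dtype=int), np.zeros(len(labeled.negatives), dtype=int)]
    return probe_feature_matrix(seqs, spec, table), y


def train_sil(
    X: np.ndarray,
    y: np.ndarray,
    config: TreeConfig | None = None,
    *,
    feature_model: str = "kmer_counting",
    k: Optional[int] = None,
    table: Optional[StructuralFeatureTable] = None,
    table_source: str = "",
) -> TrainedModel:
    """Fit the shared base classifier on one-row-per-probe features."""
    config = config or TreeConfig()
    X = np.asarray(X, dtype=float)
    est = fit_weighted_tree(X, y, None, config)
    return TrainedModel(
        base_classifier=est,
        feature_model=feature_model,
        k=k,
        classifier_config=config,
        table_source=table_source or (table.source_name if table is not None else ""),
        n_features=X.shape[1],
        table=table,
    )


def predict_sil(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Positive-class probability per probe row.

    Raises
    ------
    ConsistencyError
        If the feature length does not match the model's.
    """
    if model.feature_model == "mil3d_kmer":
        raise ConsistencyError("MIL models are scored with predict_bag, not predict_sil")
    return model.instance_probabilities(X)
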