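"""Decomposition of labelled probes into bags of weighted k-mer instances.

In the multiple-instance view of PBM data, a probe sequence is a *bag* and
every overlapping k-mer window (step 1, forward strand) is an *instance*.
A positive probe is assumed to contain at least one true binding site among
its windows; a negative probe none.  Since the binding-site location within
the probe is unknown, every instance starts with the same weight
1/(bag size) — for a 35-mer and k = 7 that is 29 instances of weight 1/29,
each carrying a 30-dimensional structural feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Sequence, Tuple

import numpy as np

from .data_io import LabeledProbeSet, Probe
from .feature_tables import StructuralFeatureTable, triplet_feature_matrix

__all__ = ["Instance", "Bag", "decompose", "build_bag", "build_bags", "reverse_complement"]

Label = Literal["positive", "negative"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Instance:
    """One k-mer window of a probe with its structural feature vector.

    ``offset`` is the 0-based start of the half-open window
    ``[offset, offset + k)`` within the probe (negative strand instances,
    when enabled, reuse the forward-strand offset of their window).
    """

    kmer: str
    offset: int
    features: np.ndarray
    weight: float


@dataclass
class Bag:
    """All k-mer instances of one labelled probe."""

    probe_id: str
    label: Label
    instances: List[Instance]
    k: int

    @property
    def feature_length(self) -> int:
        return int(self.instances[0].features.size) if self.instances else 0

    def feature_matrix(self) -> np.ndarray:
        return np.stack([inst.features for inst in self.instances])


def decompose(sequence: str, k: int) -> List[Tuple[int, str]]:
    """All overlapping k-mer windows of a sequence, left to right.

    Returns the ``L - k + 1`` pairs ``(offset, kmer)`` for step-1 sliding
    windows; a 35-mer with k = 7 yields 29 windows.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} is shorter than k = {k}")
    return [(i, sequence[i : i + k]) for i in range(len(sequence) - k + 1)]


def build_bag(
    probe: Probe,
    label: Label,
    k: int,
    table: StructuralFeatureTable,
    *,
    add_revcomp: bool = False,
) -> Bag:
    """Build the bag of weighted structural-feature instances for one probe.

    Each of the L-k+1 windows becomes an :class:`Instance` whose feature
    vector concatenates the structural parameters of its k-2 triplets
    (length (k-2)*6) and whose weight is 1/(bag size).  With
    ``add_revcomp`` the reverse-complement windows are appended as well,
    doubling the bag and halving the weights.
    """
    seq = probe.sequence.upper()
    windows = decompose(seq, k)
    sequences = [seq] + ([reverse_complement(seq)] if add_revcomp else [])
    n_instances = len(windows) * len(sequences)
    weight = 1.0 / n_instances
    instances: List[Instance] = []
    for s in sequences:
        tri = triplet_feature_matrix(s, table)  # (L-2, 6)
        for offset in range(len(s) - k + 1):
            features = tri[offset : offset + k - 2].reshape(-1).copy()
            instances.append(Instance(kmer=s[offset : offset + k], offset=offset, features=features, weight=weight))
    return Bag(probe_id=probe.probe_id, label=label, instances=instances, k=k)


def build_bags(
    labeled: LabeledProbeSet,
    k: int,
    table: StructuralFeatureTable,
    *,
    add_revcomp: bool = False,
) -> List[Bag]:
    """Bags for every probe of a labelled set (positives first)."""
    bags = [build_bag(p, "positive", k, table, add_revcomp=add_revcomp) for p in labeled.positives]
    bags += [build_bag(p, "negative", k, table, add_revcomp=add_revcomp) for p in labeled.negatives]
    return bags
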