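"""Synthetic PBM-like datasets with planted binding sites.

The generator emulates the parts of a protein-binding-microarray experiment
that this pipeline consumes: a table of short probes (default 35-mers) with
real-valued signals whose ranking separates motif-carrying probes from
background.  Positive probes receive a (possibly mutated) consensus motif at
a uniformly random, recorded offset; signals are base level + a motif
presence effect + Gaussian noise, so labelling by top/bottom signal
approximately recovers the planted classes.

A *structural twin* mode plants, in a configurable fraction of positives,
a different sequence whose structural feature vector is as close as
possible to the motif's.  Such datasets have weak sequence consensus but a
preserved structural signal — the regime in which structure-aware MIL
models are expected to retain accuracy while pure k-mer counting degrades.

All randomness flows through named substreams of one seed, so outputs are
reproducible and adding a new stream never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data_io import Probe, write_probes
from .feature_tables import StructuralFeatureTable, encode_sequence, kmer_structural_vector

__all__ = [
    "SyntheticSpec",
    "generate",
    "structural_twin_motif",
    "structural_neighborhood_variants",
    "write_dataset",
    "read_truth",
]

_BASES = np.array(list("ACGT"))

# substream ids: stable, append-only
_STREAMS = {
    "background": 0,
    "insert": 1,
    "offsets": 2,
    "mutations": 3,
    "noise": 4,
    "variant": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic PBM dataset.

    Defaults mirror the study conditions the pipeline targets: 35-base
    probes, 3000 positives and 3000 negatives, a 7-base consensus motif
    planted in every positive, uniform base composition, and signal noise
    small relative to the motif effect so signal ranking recovers the
    planted classes.
    """

    n_pos: int = 3000
    n_neg: int = 3000
    probe_length: int = 35
    motif: str = "TGACGTC"
    motif_mode: str = "consensus"  # "consensus" | "structural_neighborhood"
    n_variants: int = 16
    motif_insert_probability: float = 1.0
    mutation_rate: float = 0.0
    background_gc: float = 0.5
    base_signal: float = 0.0
    motif_signal_effect: float = 2.0
    signal_noise_sd: float = 0.3
    twin_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        encode_sequence(self.motif)
        if len(self.motif) > self.probe_length:
            raise ValueError(f"motif length {len(self.motif)} exceeds probe length {self.probe_length}")
        if not 0.0 < self.motif_insert_probability <= 1.0:
            raise ValueError("motif_insert_probability must be in (0, 1]")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must be in (0, 1)")
        if not 0.0 <= self.twin_fraction <= 1.0:
            raise ValueError("twin_fraction must be in [0, 1]")
        if self.signal_noise_sd < 0:
            raise ValueError("signal_noise_sd must be >= 0")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        if self.motif_mode not in ("consensus", "structural_neighborhood"):
            raise ValueError(f"unknown motif_mode {self.motif_mode!r}")
        if self.motif_mode == "structural_neighborhood" and self.n_variants < 1:
            raise ValueError("n_variants must be positive")


def _background_codes(rng: np.random.Generator, n: int, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=(n, length), p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def generate(
    spec: SyntheticSpec, table: Optional[StructuralFeatureTable] = None
) -> Tuple[List[Probe], Dict[str, Optional[int]]]:
    """Generate probes and the ground-truth planted offsets.

    Returns ``(probes, truth)`` where ``truth[probe_id]`` is the 0-based
    planted motif offset, or None for negatives and positives that did not
    receive an insert.  ``table`` is required when ``twin_fraction > 0``
    or in structural-neighborhood mode (the planted variants are derived
    from it).

    In ``motif_mode="structural_neighborhood"`` each positive receives one
    of the ``n_variants`` word-disjoint structural neighbours of the motif
    (uniformly at random) instead of the consensus — a dataset with weak
    sequence consensus but a preserved structural signal.
    """
    m = len(spec.motif)
    motif_codes = encode_sequence(spec.motif)
    twin_codes = None
    variant_codes = None
    if spec.motif_mode == "structural_neighborhood":
        if table is None:
            raise ValueError("structural_neighborhood mode requires a structural table")
        variants = structural_neighborhood_variants(table, spec.motif, spec.n_variants)
        variant_codes = [encode_sequence(v) for v in variants]
    elif spec.twin_fraction > 0:
        if table is None:
            raise ValueError("twin_fraction > 0 requires a structural table")
        twin_codes = encode_sequence(structural_twin_motif(table, spec.motif))

    rng_bg = _rng(spec.seed, "background")
    rng_ins = _rng(spec.seed, "insert")
    rng_off = _rng(spec.seed, "offsets")
    rng_mut = _rng(spec.seed, "mutations")
    rng_noise = _rng(spec.seed, "noise")
    rng_var = _rng(spec.seed, "variant")

    n_total = spec.n_pos + spec.n_neg
    codes = _background_codes(rng_bg, n_total, spec.probe_length, spec.background_gc)

    inserted = rng_ins.random(spec.n_pos) < spec.motif_insert_probability
    offsets = rng_off.integers(0, spec.probe_length - m + 1, size=spec.n_pos)
    if variant_codes is not None:
        variant_idx = rng_var.integers(0, len(variant_codes), size=spec.n_pos)
        use_twin = np.zeros(spec.n_pos, dtype=bool)
    else:
        variant_idx = None
        use_twin = rng_var.random(spec.n_pos) < spec.twin_fraction

    probes: List[Probe] = []
    truth: Dict[str, Optional[int]] = {}
    noise = rng_noise.normal(0.0, spec.signal_noise_sd, size=n_total) if spec.signal_noise_sd > 0 else np.zeros(n_total)

    for i in range(spec.n_pos):
        pid = f"pos_{i:05d}"
        planted: Optional[int] = None
        if inserted[i]:
            if variant_codes is not None:
                site = variant_codes[int(variant_idx[i])].copy()
            elif twin_codes is not None and use_twin[i]:
                site = twin_codes.copy()
            else:
                site = motif_codes.copy()
            if spec.mutation_rate > 0:
                mut_mask = rng_mut.random(m) < spec.mutation_rate
                if mut_mask.any():
                    shifts = rng_mut.integers(1, 4, size=int(mut_mask.sum()))
                    site[mut_mask] = (site[mut_mask] + shifts) % 4
            off = int(offsets[i])
            codes[i, off : off + m] = site
            planted = off
        signal = spec.base_signal + (spec.motif_signal_effect if planted is not None else 0.0) + noise[i]
        probes.append(Probe(probe_id=pid, sequence=_codes_to_str(codes[i]), signal=float(signal)))
        truth[pid] = planted

    for j in range(spec.n_neg):
        pid = f"neg_{j:05d}"
        i = spec.n_pos + j
        probes.append(Probe(probe_id=pid, sequence=_codes_to_str(codes[i]), signal=float(spec.base_signal + noise[i])))
        truth[pid] = None
    return probes, truth


def _all_sequence_vectors(length: int, table: StructuralFeatureTable) -> Tuple[np.ndarray, np.ndarray]:
    """Structural vectors of every DNA sequence of the given length.

    Returns (codes, vectors); enumeration order is lexicographic (A<C<G<T).
    """
    n = 4 ** length
    idx = np.arange(n)
    codes = (idx[:, None] // (4 ** np.arange(length - 1, -1, -1))) % 4
    ranks = 16 * codes[:, :-2] + 4 * codes[:, 1:-1] + codes[:, 2:]
    vectors = table.values[ranks].reshape(n, -1)
    return codes, vectors


def structural_twin_motif(table: StructuralFeatureTable, motif: str) -> str:
    """A different sequence of equal length with the closest structural vector.

    For motifs of length <= 7 the search is exhaustive over all 4^L
    candidates; longer motifs use a greedy search over all single-position
    substitutions.  Ties are broken toward the lexicographically smallest
    candidate (A < C < G < T); the motif itself is excluded, so the result
    always differs from the input.
    """
    motif = motif.upper()
    target = kmer_structural_vector(motif, table)
    L = len(motif)
    if L <= 7:
        codes, vectors = _all_sequence_vectors(L, table)
        d2 = ((vectors - target) ** 2).sum(axis=1)
        self_rank = 0
        for c in encode_sequence(motif):
            self_rank = self_rank * 4 + int(c)
        d2[self_rank] = np.inf
        best = int(np.argmin(d2))  # first minimum = lexicographically smallest
        return _codes_to_str(codes[best])
    # greedy: best single-base substitution, candidates in lexicographic order
    base_codes = encode_sequence(motif)
    candidates = []
    for pos in range(L):
        for b in range(4):
            if b == base_codes[pos]:
                continue
            cand = base_codes.copy()
            cand[pos] = b
            candidates.append(cand)
    cand_arr = np.stack(candidates)
    ranks = 16 * cand_arr[:, :-2] + 4 * cand_arr[:, 1:-1] + cand_arr[:, 2:]
    vectors = table.values[ranks].reshape(len(candidates), -1)
    d2 = ((vectors - target) ** 2).sum(axis=1)
    order = sorted(range(len(candidates)), key=lambda i: (d2[i], _codes_to_str(cand_arr[i])))
    return _codes_to_str(cand_arr[order[0]])


def _shares_aligned_kmer(a: np.ndarray, b: np.ndarray, k: int) -> bool:
    match = a == b
    return any(bool(match[i : i + k].all()) for i in range(a.size - k + 1))


def structural_neighborhood_variants(
    table: StructuralFeatureTable,
    motif: str,
    n_variants: int,
    *,
    lexical_exclusion_k: int = 5,
) -> List[str]:
    """Word-disjoint sequences closest to the motif in structural-feature space.

    Candidates of the motif's length are ranked by Euclidean distance
    between structural vectors (exhaustive enumeration; motif length <= 8)
    and picked greedily, skipping any candidate that shares an aligned
    k-mer of length ``lexical_exclusion_k`` with the motif or with an
    already-picked variant.  The result is a set of lexically unrelated
    words — no common length-5 subword for a k-mer-counting model to latch
    onto — that nonetheless sit close to the motif's structural profile:
    the planted signal of a weak-consensus dataset.
    """
    L = len(motif)
    if L > 8:
        raise ValueError(f"structural neighbourhood search supports motif length <= 8, got {L}")
    if lexical_exclusion_k > L:
        raise ValueError("lexical_exclusion_k cannot exceed the motif length")
    target = kmer_structural_vector(motif, table)
    codes, vectors = _all_sequence_vectors(L, table)
    d2 = ((vectors - target) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")  # lexicographic tie-break via stable sort
    chosen = [encode_sequence(motif)]
    out: List[str] = []
    for i in order:
        cand = codes[i]
        if any(_shares_aligned_kmer(cand, prev, lexical_exclusion_k) for prev in chosen):
            continue
        chosen.append(cand)
        out.append(_codes_to_str(cand))
        if len(out) >= n_variants:
            break
    if len(out) < n_variants:
        raise ValueError(f"only {len(out)} disjoint variants exist for motif {motif!r}")
    return out


def write_dataset(
    out_dir: str | Path,
    probes: List[Probe],
    truth: Dict[str, Optional[int]],
    *,
    prefix: str = "probes",
) -> Tuple[Path, Path]:
    """Write the probe TSV (data_io dialect) and a truth TSV ``probe_id<TAB>offset``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probes_path = out_dir / f"{prefix}.tsv"
    truth_path = out_dir / f"{prefix}.truth.tsv"
    write_probes(probes_path, probes)
    with open(truth_path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\toffset\n")
        for p in probes:
            off = truth.get(p.probe_id)
            fh.write(f"{p.probe_id}\t{'' if off is None else off}\n")
    return probes_path, truth_path


def read_truth(path: str | Path) -> Dict[str, Optional[int]]:
    truth: Dict[str, Optional[int]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            pid, _, off = line.rstrip("\n").partition("\t")
            truth[pid] = int(off) if off else None
    return truth
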