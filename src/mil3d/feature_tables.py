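"""Trinucleotide structural-parameter tables and k-mer feature vectors.

DNA conformation can be summarised, per trinucleotide, by six real-valued
base parameters of the middle base pair — shear, buckle, stretch, propeller,
stagger and opening — estimated from molecular-dynamics simulations of short
oligomers.  A :class:`StructuralFeatureTable` holds one 6-vector for each of
the 64 possible 3-mers.  Any k-mer (k >= 3) is mapped to a feature vector by
concatenating the table rows of its k-2 overlapping triplets, left to right,
giving a vector of length (k-2)*6.

The package ships a clearly labelled *placeholder* table (fixed-seed
pseudo-random values in physically plausible ranges) so the pipeline runs
out of the box; real MD-derived tables are supplied by the user in the same
TSV format and are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidSequenceError, TableFormatError

__all__ = [
    "STRUCTURAL_PARAMETERS",
    "ALL_TRIMERS",
    "StructuralFeatureTable",
    "load_structural_table",
    "load_placeholder_table",
    "kmer_structural_vector",
    "triplet_feature_matrix",
    "encode_sequence",
]

#: Fixed column order of the six base parameters.
STRUCTURAL_PARAMETERS = ("shear", "buckle", "stretch", "propeller", "stagger", "opening")

_BASES = "ACGT"

#: All 64 trinucleotides in lexicographic order (A < C < G < T).
ALL_TRIMERS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

# 256-entry lookup: ASCII byte -> base code 0..3, -1 for anything else.
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a DNA string as base codes A=0, C=1, G=2, T=3 (case-insensitive).

    Raises
    ------
    InvalidSequenceError
        If the sequence contains any character outside A/C/G/T.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_LUT[raw]
    bad = np.flatnonzero(codes < 0)
    if bad.size:
        pos = int(bad[0])
        raise InvalidSequenceError(
            f"invalid base {sequence[pos]!r} at position {pos} (only A/C/G/T allowed)"
        )
    return codes.astype(np.intp)


def _triplet_ranks(codes: np.ndarray) -> np.ndarray:
    """Lexicographic rank (0..63) of every overlapping triplet."""
    return 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]


@dataclass(frozen=True)
class StructuralFeatureTable:
    """Lookup from each of the 64 trinucleotides to six base parameters.

    ``values`` is a (64, 6) float array whose row *i* holds the parameters of
    the trinucleotide with lexicographic rank *i* (A < C < G < T), columns in
    the fixed order :data:`STRUCTURAL_PARAMETERS`.
    """

    values: np.ndarray
    source_name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (64, 6):
            raise TableFormatError(f"expected a 64 x 6 matrix, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise TableFormatError("structural table contains non-finite values")
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @classmethod
    def from_mapping(cls, entries: Mapping[str, np.ndarray], source_name: str = "") -> "StructuralFeatureTable":
        """Build a table from a ``{3-mer: 6-vector}`` mapping (must be complete)."""
        upper = {k.upper(): np.asarray(v, dtype=float) for k, v in entries.items()}
        if len(upper) != len(entries):
            dupes = sorted({k.upper() for k in entries if list(entries).count(k) > 1})
            raise TableFormatError(f"duplicate 3-mer after case folding: {dupes}")
        missing = [t for t in ALL_TRIMERS if t not in upper]
        if missing:
            raise TableFormatError(f"missing 3-mer(s): {', '.join(missing[:5])}")
        extra = sorted(set(upper) - set(ALL_TRIMERS))
        if extra:
            raise TableFormatError(f"unexpected 3-mer(s): {', '.join(extra[:5])}")
        values = np.stack([upper[t] for t in ALL_TRIMERS])
        return cls(values=values, source_name=source_name)

    @property
    def entries(self) -> Dict[str, np.ndarray]:
        """The table as a ``{3-mer: 6-vector}`` dictionary."""
        return {t: self.values[i] for i, t in enumerate(ALL_TRIMERS)}

    def row(self, trimer: str) -> np.ndarray:
        """The 6-vector of one trinucleotide (case-insensitive)."""
        codes = encode_sequence(trimer)
        if codes.size != 3:
            raise ValueError(f"expected a 3-mer, got {trimer!r}")
        return self.values[int(_triplet_ranks(codes)[0])]

    def to_frame(self) -> pd.DataFrame:
        """The table as a DataFrame with a ``kmer`` column, lexicographic order."""
        df = pd.DataFrame(self.values, columns=list(STRUCTURAL_PARAMETERS))
        df.insert(0, "kmer", list(ALL_TRIMERS))
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def load_structural_table(path: str | Path, source_name: str | None = None) -> StructuralFeatureTable:
    """Load a structural-parameter table from a tab-separated file.

    The file must have a header line naming the six parameters
    (``kmer shear buckle stretch propeller stagger opening``) followed by one
    row per trinucleotide.  3-mers are normalised to uppercase.

    Raises
    ------
    TableFormatError
        Wrong column count, wrong header, or a missing/duplicate 3-mer
        (the error names the offending 3-mer).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except OSError as exc:
        raise TableFormatError(f"cannot read structural table {path}: {exc}") from exc
    expected_cols = ["kmer", *STRUCTURAL_PARAMETERS]
    got = [c.strip().lower() for c in df.columns]
    if len(got) != 7:
        raise TableFormatError(f"{path}: expected 7 tab-separated columns, got {len(got)}")
    if got != expected_cols:
        raise TableFormatError(f"{path}: header must be {expected_cols}, got {got}")

    kmers = df["kmer"].astype(str).str.strip().str.upper()
    seen: Dict[str, int] = {}
    for i, t in enumerate(kmers):
        if t in seen:
            raise TableFormatError(f"{path}: duplicate 3-mer {t!r} (rows {seen[t] + 2} and {i + 2})")
        seen[t] = i
    missing = [t for t in ALL_TRIMERS if t not in seen]
    if missing:
        raise TableFormatError(f"{path}: missing 3-mer {missing[0]!r}" + (f" (+{len(missing) - 1} more)" if len(missing) > 1 else ""))
    unknown = sorted(set(seen) - set(ALL_TRIMERS))
    if unknown:
        raise TableFormatError(f"{path}: unrecognised 3-mer {unknown[0]!r}")

    values = np.empty((64, 6), dtype=float)
    for row_i, trimer in enumerate(kmers):
        rank = ALL_TRIMERS.index(trimer)
        for col_j, col in enumerate(STRUCTURAL_PARAMETERS):
            cell = df.iloc[row_i][col]
            try:
                values[rank, col_j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise TableFormatError(
                    f"{path}: non-numeric value {cell!r} at row {row_i + 2}, column {col!r}"
                ) from exc
    return StructuralFeatureTable(values=values, source_name=source_name or path.name)


def load_placeholder_table() -> StructuralFeatureTable:
    """Load the packaged placeholder table (synthetic values, fixed seed).

    These are NOT measured structural parameters; they are reproducible
    pseudo-random values in plausible physical ranges, shipped so that the
    pipeline is runnable and testable without external data.  Substitute a
    real MD-derived table via :func:`load_structural_table` for any
    scientific use.
    """
    with resources.as_file(resources.files("mil3d.data") / "placeholder_structural_table.tsv") as p:
        table = load_structural_table(p, source_name="placeholder-fixture")
    return table


def kmer_structural_vector(kmer: str, table: StructuralFeatureTable) -> np.ndarray:
    """Structural feature vector of a k-mer: concatenated triplet rows.

    For a k-mer with k >= 3 the result has length (k-2)*6; slice
    ``[6*i, 6*i+6)`` is the table row of the i-th overlapping triplet.
    """
    codes = encode_sequence(kmer)
    if codes.size < 3:
        raise ValueError(f"k-mer must have length >= 3, got {codes.size}")
    return table.values[_triplet_ranks(codes)].reshape(-1)


def triplet_feature_matrix(sequence: str, table: StructuralFeatureTable) -> np.ndarray:
    """(L-2, 6) matrix of per-triplet parameters for a whole sequence.

    Row *i* is the table row of the triplet starting at position *i*.  Used
    to build all window vectors of a probe without repeated lookups.
    """
    codes = encode_sequence(sequence)
    if codes.size < 3:
        raise ValueError(f"sequence must have length >= 3, got {codes.size}")
    return table.values[_triplet_ranks(codes)]
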