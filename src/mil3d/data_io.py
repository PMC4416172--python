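"""Reading PBM probe tables and signal-based labelling.

A protein-binding microarray (PBM) reports, for each of ~40,000 designed
probe sequences (nominally 35 bases), a real-valued signal proportional to
the relative binding affinity of the assayed transcription factor.  The
classification data set is built by taking the ``n_pos`` highest-signal
probes as positives and the ``n_neg`` lowest-signal probes as negatives
(3000 each by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence

from .errors import InvalidSequenceError, ProbeParseError
from .feature_tables import encode_sequence

__all__ = ["Probe", "LabeledProbeSet", "read_probes", "read_probes_fasta", "write_probes", "label_by_signal"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Probe:
    """One PBM probe: identifier, DNA sequence and binding signal."""

    probe_id: str
    sequence: str
    signal: float


@dataclass
class LabeledProbeSet:
    """Top/bottom-signal labelled probes for one transcription factor."""

    positives: List[Probe]
    negatives: List[Probe]
    tf_name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        overlap = {p.probe_id for p in self.positives} & {p.probe_id for p in self.negatives}
        if overlap:
            raise ValueError(f"probes labelled both positive and negative: {sorted(overlap)[:5]}")


def _is_valid_sequence(seq: str) -> bool:
    try:
        encode_sequence(seq)
    except InvalidSequenceError:
        return False
    return len(seq) > 0


def read_probes(
    path: str | Path,
    *,
    header: bool | str = "auto",
    strict_length: int | None = None,
) -> List[Probe]:
    """Read a tab-separated probe table ``probe_id<TAB>sequence<TAB>signal``.

    Probes whose sequence contains any non-A/C/G/T character are dropped
    with a logged count; input order is preserved otherwise.  ``header``
    may be True, False, or ``"auto"`` (skip the first line iff its third
    column is not numeric).  ``strict_length`` enforces an exact sequence
    length (e.g. 35) when given.

    Raises
    ------
    ProbeParseError
        Malformed row or non-numeric signal (reported with line number).
    OSError
        Unreadable file.
    """
    path = Path(path)
    probes: List[Probe] = []
    dropped = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ProbeParseError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
            probe_id, sequence, signal_str = (p.strip() for p in parts)
            if lineno == 1 and header in (True, "auto"):
                try:
                    float(signal_str)
                except ValueError:
                    continue  # header line
                if header is True:
                    continue
            try:
                signal = float(signal_str)
            except ValueError as exc:
                raise ProbeParseError(f"{path}:{lineno}: non-numeric signal {signal_str!r}") from exc
            sequence = sequence.upper()
            if not _is_valid_sequence(sequence):
                dropped += 1
                continue
            if strict_length is not None and len(sequence) != strict_length:
                raise ProbeParseError(
                    f"{path}:{lineno}: sequence length {len(sequence)} != required {strict_length}"
                )
            probes.append(Probe(probe_id=probe_id, sequence=sequence, signal=signal))
    if dropped:
        logger.warning("%s: dropped %d probe(s) with non-ACGT sequences", path, dropped)
    return probes


def read_probes_fasta(path: str | Path, signals: Mapping[str, float]) -> List[Probe]:
    """Read probe sequences from FASTA, with signals supplied separately.

    ``signals`` maps FASTA record ids to binding signals; records without a
    signal, or with non-ACGT sequences, are dropped with a logged count.
    """
    from Bio import SeqIO

    probes: List[Probe] = []
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id not in signals or not _is_valid_sequence(seq):
            dropped += 1
            continue
        probes.append(Probe(probe_id=rec.id, sequence=seq, signal=float(signals[rec.id])))
    if dropped:
        logger.warning("%s: dropped %d FASTA record(s) (missing signal or non-ACGT)", path, dropped)
    return probes


def write_probes(path: str | Path, probes: Iterable[Probe], *, header: bool = True) -> None:
    """Write probes in the same TSV dialect :func:`read_probes` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("probe_id\tsequence\tsignal\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.sequence}\t{p.signal!r}\n")


def label_by_signal(
    probes: Sequence[Probe],
    n_pos: int = 3000,
    n_neg: int = 3000,
    *,
    tf_name: str = "",
    source: str = "",
) -> LabeledProbeSet:
    """Label the ``n_pos`` highest-signal probes positive and the ``n_neg`` lowest negative.

    Ties at either selection boundary are broken deterministically by
    ``probe_id`` (ascending), so the result is invariant to input order;
    negatives are drawn from the probes left after the positive selection,
    keeping the two sets disjoint even when ties span both cut points.

    Raises
    ------
    ValueError
        If ``n_pos + n_neg`` exceeds the number of probes (the selections
        would overlap) or either count is not positive.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    if n_pos + n_neg > len(probes):
        raise ValueError(f"n_pos + n_neg = {n_pos + n_neg} exceeds available probes ({len(probes)})")
    by_desc = sorted(probes, key=lambda p: (-p.signal, p.probe_id))
    positives = by_desc[:n_pos]
    negatives = sorted(by_desc[n_pos:], key=lambda p: (p.signal, p.probe_id))[:n_neg]
    return LabeledProbeSet(positives=positives, negatives=negatives, tf_name=tf_name, source=source)
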