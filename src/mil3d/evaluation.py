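"""Benchmarking and analysis: AUC, top high-probability k-mers, correlations.

The benchmark trains each requested feature model on one array's labelled
probes and scores a second, disjoint array, reporting the area under the
ROC curve per (TF, model).  For the MIL model it additionally tabulates the
most frequent high-probability k-mers among positive test probes — a strong
consensus motif shows up as a few dominating k-mers with a high total
occurrence — and, across TFs, correlates the MIL-over-counting AUC gain
with that total and with probe GC content.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._tree import TreeConfig
from .bags import build_bags
from .baselines import FeatureModelSpec, features_and_labels, predict_sil, train_sil
from .data_io import LabeledProbeSet
from .errors import UndefinedStatisticError
from .feature_tables import StructuralFeatureTable, encode_sequence
from .mil_wrapper import instance_scores, predict_bags, train

__all__ = [
    "EvaluationReport",
    "KmerFrequencyTable",
    "TfDataset",
    "auc",
    "top_kmers",
    "gc_content",
    "localization_hit_rate",
    "pearson",
    "paired_ttest",
    "benchmark",
]


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney formulation; ties count 1/2).

    Raises
    ------
    UndefinedStatisticError
        If only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if np.unique(labels).size < 2:
        raise UndefinedStatisticError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, scores))


@dataclass
class KmerFrequencyTable:
    """Occurrence counts of the most frequent high-probability k-mers."""

    tf_name: str
    rows: List[Tuple[str, int]]
    probability_threshold: float
    total: int

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("kmer\toccurrences\n")
            for kmer, count in self.rows:
                fh.write(f"{kmer}\t{count}\n")
            fh.write(f"Total\t{self.total}\n")


def top_kmers(
    scored_instances: Sequence[Tuple[str, int, str, float]],
    *,
    threshold: float = 0.85,
    top_n: int = 10,
    tf_name: str = "",
) -> KmerFrequencyTable:
    """Most frequent k-mers among instances scoring at or above ``threshold``.

    ``scored_instances`` is the output of
    :func:`mil3d.mil_wrapper.instance_scores`, typically restricted to
    positive test bags.  Occurrences are counted per qualifying instance
    (a probe may contribute several), rows are sorted by count descending
    with ties broken by lexicographic k-mer order, and ``total`` sums the
    kept rows.
    """
    counts = Counter(kmer for (_pid, _off, kmer, prob) in scored_instances if prob >= threshold)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[: max(top_n, 0)]
    return KmerFrequencyTable(
        tf_name=tf_name,
        rows=rows,
        probability_threshold=threshold,
        total=int(sum(c for _, c in rows)),
    )


def localization_hit_rate(
    bags,
    predictions,
    truth: Dict[str, Optional[int]],
    motif_length: int,
    *,
    min_overlap: Optional[int] = None,
) -> float:
    """Fraction of positive bags whose top-scoring window recovers the planted site.

    The highest-probability instance of a bag counts as a hit when its
    window overlaps the planted motif ``[offset, offset + motif_length)``
    by at least ``min_overlap`` bases (default: a majority of the window,
    ``(k + 1) // 2``).  Overlap rather than exact-offset equality is used
    because windows overlapping a binding site are themselves partial
    sites and may legitimately tie the full-site window's probability.
    Bags without a recorded planted offset are skipped.
    """
    hits = total = 0
    for bag, pred in zip(bags, predictions):
        offset = truth.get(bag.probe_id)
        if offset is None:
            continue
        k = bag.k
        need = min_overlap if min_overlap is not None else (k + 1) // 2
        top = int(np.argmax(pred.instance_probabilities))
        overlap = max(0, min(top + k, offset + motif_length) - max(top, offset))
        total += 1
        hits += int(overlap >= need)
    if total == 0:
        raise UndefinedStatisticError("no bags with a recorded planted offset")
    return hits / total


def gc_content(sequence: str) -> float:
    """Fraction of G/C bases, in [0, 1]."""
    if not sequence:
        raise ValueError("gc_content of an empty sequence is undefined")
    codes = encode_sequence(sequence)
    return float(np.mean((codes == 1) | (codes == 2)))


def pearson(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-distribution p-value.

    Raises
    ------
    UndefinedStatisticError
        Fewer than 3 points or zero variance in either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise UndefinedStatisticError("Pearson correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("Pearson correlation is undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_ttest(auc_a: Sequence[float], auc_b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test on per-TF score differences.

    Identical lists (all differences zero) return (0.0, 1.0): no evidence
    of a difference.  Zero-variance differences with a nonzero mean are
    degenerate (the statistic diverges) and raise.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise UndefinedStatisticError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise UndefinedStatisticError("paired t-test is degenerate: constant nonzero differences")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class TfDataset:
    """Disjoint train/test labelled probe sets for one transcription factor."""

    tf_name: str
    train: LabeledProbeSet
    test: LabeledProbeSet


@dataclass
class EvaluationReport:
    """Per-TF, per-model AUCs plus the cross-TF analyses."""

    per_model_auc: Dict[str, Dict[str, float]] = field(default_factory=dict)  # tf -> model label -> AUC
    paired_test: Optional[Tuple[str, str, float, float]] = None  # (model_a, model_b, t, p)
    correlations: List[Tuple[str, str, float, float]] = field(default_factory=list)  # (x, y, r, p)
    top_kmer_tables: Dict[str, KmerFrequencyTable] = field(default_factory=dict)
    errors: Dict[str, str] = field(default_factory=dict)  # "tf/model" -> message

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "per_model_auc": {tf: dict(sorted(models.items())) for tf, models in sorted(self.per_model_auc.items())},
            "paired_test": list(self.paired_test) if self.paired_test else None,
            "correlations": [list(c) for c in self.correlations],
            "top_kmer_tables": {
                tf: {
                    "tf_name": t.tf_name,
                    "rows": [[k, c] for k, c in t.rows],
                    "probability_threshold": t.probability_threshold,
                    "total": t.total,
                }
                for tf, t in sorted(self.top_kmer_tables.items())
            },
            "errors": dict(sorted(self.errors.items())),
        }
        text = json.dumps(payload, indent=2, sort_keys=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "EvaluationReport":
        if isinstance(text_or_path, Path) or (isinstance(text_or_path, str) and "\n" not in text_or_path and Path(text_or_path).exists()):
            text = Path(text_or_path).read_text(encoding="utf-8")
        else:
            text = str(text_or_path)
        payload = json.loads(text)
        return cls(
            per_model_auc={tf: dict(models) for tf, models in payload["per_model_auc"].items()},
            paired_test=tuple(payload["paired_test"]) if payload.get("paired_test") else None,
            correlations=[tuple(c) for c in payload.get("correlations", [])],
            top_kmer_tables={
                tf: KmerFrequencyTable(
                    tf_name=t["tf_name"],
                    rows=[(k, int(c)) for k, c in t["rows"]],
                    probability_threshold=float(t["probability_threshold"]),
                    total=int(t["total"]),
                )
                for tf, t in payload.get("top_kmer_tables", {}).items()
            },
            errors=dict(payload.get("errors", {})),
        )

    def auc_matrix_tsv(self, path: str | Path) -> None:
        """Human-readable TF x model AUC matrix."""
        models = sorted({m for row in self.per_model_auc.values() for m in row})
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("tf\t" + "\t".join(models) + "\n")
            for tf in sorted(self.per_model_auc):
                row = self.per_model_auc[tf]
                fh.write(tf + "\t" + "\t".join(f"{row[m]:.4f}" if m in row else "NA" for m in models) + "\n")


def _fit_and_score(
    spec: FeatureModelSpec,
    ds: TfDataset,
    table: Optional[StructuralFeatureTable],
    config: TreeConfig,
) -> Tuple[float, Optional[List[Tuple[str, int, str, float]]]]:
    """AUC on the test set; MIL models also return positive-bag instance scores."""
    if spec.name == "mil3d_kmer":
        if table is None:
            raise ValueError("MIL structural models require a structural table")
        train_bags = build_bags(ds.train, spec.k, table)
        model = train(train_bags, config, table=table)
        test_bags = build_bags(ds.test, spec.k, table)
        preds = predict_bags(model, test_bags)
        y = np.array([1 if b.label == "positive" else 0 for b in test_bags])
        scores = np.array([p.bag_probability for p in preds])
        pos_bags = [b for b in test_bags if b.label == "positive"]
        return auc(y, scores), instance_scores(model, pos_bags)
    X_train, y_train = features_and_labels(ds.train, spec, table)
    model = train_sil(X_train, y_train, config, feature_model=spec.name, k=spec.k, table=table)
    X_test, y_test = features_and_labels(ds.test, spec, table)
    return auc(y_test, predict_sil(model, X_test)), None


def benchmark(
    datasets: Sequence[TfDataset],
    models: Sequence[FeatureModelSpec | str],
    table: Optional[StructuralFeatureTable] = None,
    config: TreeConfig | None = None,
    *,
    top_kmer_threshold: float = 0.85,
    top_n: int = 10,
    paired_pair: Tuple[str, str] = ("mil3d_k7", "count_5"),
) -> EvaluationReport:
    """Train every requested model per TF, score the held-out array, analyse.

    Per-model failures are captured in ``report.errors`` rather than
    aborting the whole run.  When at least three TFs have both models of
    ``paired_pair``, the report includes the paired t-test between them and
    the Pearson correlations of the AUC gain with (a) the total occurrence
    of the top high-probability k-mers and (b) the mean GC content of
    positive test probes.
    """
    from .baselines import parse_model_spec  # local to avoid cycle at import time

    config = config or TreeConfig()
    specs = [parse_model_spec(m) if isinstance(m, str) else m for m in models]
    report = EvaluationReport()
    for ds in datasets:
        report.per_model_auc.setdefault(ds.tf_name, {})
        for spec in specs:
            try:
                score, scored = _fit_and_score(spec, ds, table, config)
            except Exception as exc:  # per-model fail-fast with capture
                report.errors[f"{ds.tf_name}/{spec.label}"] = f"{type(exc).__name__}: {exc}"
                continue
            report.per_model_auc[ds.tf_name][spec.label] = score
            if scored is not None and spec.label == paired_pair[0]:
                report.top_kmer_tables[ds.tf_name] = top_kmers(
                    scored, threshold=top_kmer_threshold, top_n=top_n, tf_name=ds.tf_name
                )

    a_label, b_label = paired_pair
    complete = [
        ds.tf_name
        for ds in datasets
        if a_label in report.per_model_auc.get(ds.tf_name, {}) and b_label in report.per_model_auc.get(ds.tf_name, {})
    ]
    if len(complete) >= 2:
        a = [report.per_model_auc[tf][a_label] for tf in complete]
        b = [report.per_model_auc[tf][b_label] for tf in complete]
        try:
            t, p = paired_ttest(a, b)
            report.paired_test = (a_label, b_label, t, p)
        except UndefinedStatisticError:
            pass
    if len(complete) >= 3:
        gains = [report.per_model_auc[tf][a_label] - report.per_model_auc[tf][b_label] for tf in complete]
        ds_by_name = {ds.tf_name: ds for ds in datasets}
        if all(tf in report.top_kmer_tables for tf in complete):
            totals = [float(report.top_kmer_tables[tf].total) for tf in complete]
            try:
                r, p = pearson(totals, gains)
                report.correlations.append(("top_kmer_total", f"gain_{a_label}_over_{b_label}", r, p))
            except UndefinedStatisticError:
                pass
        gc_means = [
            float(np.mean([gc_content(pr.sequence) for pr in ds_by_name[tf].test.positives])) for tf in complete
        ]
        try:
            r, p = pearson(gc_means, gains)
            report.correlations.append(("mean_gc_positive_test", f"gain_{a_label}_over_{b_label}", r, p))
        except UndefinedStatisticError:
            pass
    return report
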