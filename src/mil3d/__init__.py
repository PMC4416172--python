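"""mil3d — structure-based multiple-instance learning for in vitro TF-DNA binding.

Predicts protein-binding-microarray (PBM) probe binding from DNA
trinucleotide structural parameters.  Each probe is a *bag* of overlapping
k-mer *instances*; a wrapper MIL algorithm trains a weighted decision tree
on the flattened instances and scores a probe by averaging its instances'
class probabilities.  Single-instance baselines (positional structural
concatenation and k-mer counting), an evaluation suite, and a synthetic
planted-motif data generator are included.
"""

from . import bags, baselines, cli, data_io, evaluation, feature_tables, mil_wrapper, synthetic_data
from ._tree import TreeConfig
from .bags import Bag, Instance, build_bag, build_bags, decompose
from .baselines import (
    FeatureModelSpec,
    combined_count_features,
    kmer_count_features,
    parse_model_spec,
    sil3d_features,
)
from .data_io import LabeledProbeSet, Probe, label_by_signal, read_probes, write_probes
from .evaluation import (
    EvaluationReport,
    KmerFrequencyTable,
    TfDataset,
    auc,
    benchmark,
    gc_content,
    localization_hit_rate,
    paired_ttest,
    pearson,
    top_kmers,
)
from .feature_tables import (
    StructuralFeatureTable,
    kmer_structural_vector,
    load_placeholder_table,
    load_structural_table,
)
from .mil_wrapper import (
    BagPrediction,
    TrainedModel,
    flatten,
    instance_scores,
    load_model,
    predict_bag,
    predict_bags,
    save_model,
    train,
)
from .synthetic_data import (
    SyntheticSpec,
    generate,
    structural_neighborhood_variants,
    structural_twin_motif,
)

__version__ = "0.1.0"

__all__ = [
    "Bag",
    "BagPrediction",
    "EvaluationReport",
    "FeatureModelSpec",
    "Instance",
    "KmerFrequencyTable",
    "LabeledProbeSet",
    "Probe",
    "StructuralFeatureTable",
    "SyntheticSpec",
    "TfDataset",
    "TrainedModel",
    "TreeConfig",
    "auc",
    "benchmark",
    "build_bag",
    "build_bags",
    "combined_count_features",
    "decompose",
    "flatten",
    "gc_content",
    "generate",
    "instance_scores",
    "kmer_count_features",
    "kmer_structural_vector",
    "label_by_signal",
    "load_model",
    "localization_hit_rate",
    "load_placeholder_table",
    "load_structural_table",
    "paired_ttest",
    "parse_model_spec",
    "pearson",
    "predict_bag",
    "predict_bags",
    "read_probes",
    "save_model",
    "sil3d_features",
    "structural_neighborhood_variants",
    "structural_twin_motif",
    "top_kmers",
    "train",
    "write_probes",
]
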