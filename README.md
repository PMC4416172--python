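# mil3d — structure-based multiple-instance learning for TF–DNA binding

`mil3d` predicts *in vitro* transcription-factor binding of
protein-binding-microarray (PBM) probes from the three-dimensional
structural properties of DNA, using multiple-instance learning (MIL).
It is aimed at regulatory-genomics researchers who want a
position-independent, structure-aware alternative to k-mer counting for
modelling transcription-factor binding sites (TFBS), plus the baselines
and analyses needed to compare the two.

## The model

A PBM probe (a 35-mer with a real-valued binding signal) is a **bag**; its
L−k+1 overlapping k-mer windows are **instances** (k ∈ [5, 8]).  A bag is
labelled positive/negative by taking the 3,000 highest/lowest-signal
probes of an array.  Each instance is mapped to a structural feature
vector by looking up, for each of its k−2 triplets, six base parameters of
the central base pair (shear, buckle, stretch, propeller, stagger,
opening) in a 64 × 6 trinucleotide table, and concatenating the rows —
length (k−2)·6, e.g. 30 for k = 7.

The wrapper MIL algorithm flattens bags for training — every instance gets
its bag's label and weight 1/(L−k+1) — and fits a weighted decision tree
with Laplace-smoothed leaf probabilities.  A bag is scored by the
arithmetic mean of its instances' positive-class probabilities

p(bag) = (1 / |B|) Σᵢ∈B p(xᵢ),

and the per-instance p(xᵢ) within positive bags rank candidate binding
sites.  Baselines trained with the same base classifier: **SIL3D**
(positional concatenation of all 33 triplet rows of the probe, length
198), **k-mer counting** (counts of all 4^k words) and **3+4+5-mer
counting** (length 64+256+1024 = 1344).  Evaluation is by ROC AUC on a
held-out array, with top-scoring-7-mer frequency tables, Pearson
correlations of the MIL-over-counting gain against consensus strength and
GC content, and a paired t-test across TFs.

The 64 × 6 table of MD-derived parameters is an external input; the
package ships a clearly-labelled synthetic placeholder so everything runs
out of the box (see `docs/methods.md`), and any real table in the same
TSV format can be substituted.

## Worked example

Simulate two PBM-like arrays with the motif `TGACGTC` planted in the
positives, then benchmark all four feature models (training on the first
array, scoring the second):

```bash
mil3d simulate --out-dir demo       --n-pos 150 --n-neg 150 --seed 11
mil3d simulate --out-dir demo_test  --n-pos 150 --n-neg 150 --seed 12
mil3d benchmark --train demo/probes.tsv --test demo_test/probes.tsv \
    --tf-name SIM --models mil3d_k7,sil3d,count_5,count345 \
    --n-pos 150 --n-neg 150 --out-dir demo_bench
```

prints (placeholder structural table, so a warning precedes it):

```
SIM     count345        AUC=0.9696
SIM     count_5         AUC=0.9963
SIM     mil3d_k7        AUC=0.9880
SIM     sil3d           AUC=0.5262
```

With a strong planted consensus both MIL3D and counting are near-perfect,
while SIL3D fails (≈0.53): its positional concatenation assumes each
probe position contributes identically, which a randomly placed site
violates.  The benchmark also writes `demo_bench/top_kmers_SIM.tsv`, the
most frequent 7-mers among instances predicted to bind with probability
≥ 0.85 in positive test probes:

```
kmer    occurrences
TGACGTC 150
ACCTCCT 1
TCGGGTC 1
...
Total   153
```

The planted motif dominates — the instance-level probabilities have
localized the binding site (the top-scoring window overlaps the planted
site in ≈99% of positive bags here).  The interesting regime is weak
sequence consensus: `mil3d simulate --motif-mode structural_neighborhood`
plants 16 word-disjoint structural neighbours of the motif instead of one
consensus, where counting drops toward AUC ≈ 0.6 while MIL3D retains
≈ 0.75 by exploiting structural similarity alone.

The same pipeline runs from Python (`mil3d.generate`,
`mil3d.label_by_signal`, `mil3d.build_bags`, `mil3d.train`,
`mil3d.benchmark`, ...); the CLI is a thin layer over those functions.

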