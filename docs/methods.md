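# Methods

## Problem and model

A protein-binding microarray (PBM) measures the relative affinity of one
transcription factor (TF) for each of ~40,000 designed probe sequences of
35 bases.  The task is binary: given a probe's sequence, predict whether it
is among the strongest-bound probes.  The positive class is the 3,000
highest-signal probes, the negative class the 3,000 lowest-signal probes;
training and evaluation use two disjoint probe tables (emulating two
independent array designs), never cross-validation within one table.

The binding site is a short (~6–12 bp) subsequence at an unknown position
within the probe.  This is a multiple-instance learning (MIL) problem: a
probe is a *bag* of its L−k+1 overlapping k-mer windows (*instances*,
k ∈ [5, 8] by default), a positive bag is assumed to contain at least one
true site, a negative bag none.

Each instance is described not by its letters but by the DNA's local
three-dimensional conformation: a lookup table assigns each of the 64
trinucleotides six real-valued base parameters of its middle base pair —
shear, buckle, stretch, propeller, stagger, opening — estimated from
molecular-dynamics simulation of short oligomers.  A k-mer's feature
vector concatenates the rows of its k−2 overlapping triplets, left to
right, length (k−2)·6 (30 for k = 7).

### The wrapper MIL classifier

Training flattens the bags: every instance inherits its bag's label and an
initial weight of 1/(bag size) — 1/29 for a 35-mer at k = 7 — expressing
that every window is a priori equally likely to be the site.  A standard
probabilistic classifier is fitted on the weighted rows.  At prediction
time a bag's positive-class probability is the **unweighted arithmetic
mean** of its instances' probabilities; training-time weights are not
reused.  Instance-level probabilities within positive bags are exposed for
binding-site localization: the top-scoring windows are the model's
candidate sites.

An optional, experimental iterative-reweighting mode (off by default)
refits the tree a fixed number of times with per-bag-renormalised weights
proportional to the previous model's instance probabilities (their
complement in negative bags).  The single-pass fit is the reference
behaviour.

### Base classifier

The base learner is a CART decision tree (scikit-learn) fitted with
per-instance sample weights.  It is chosen for the same reasons a C4.5
tree suits this comparison — insensitive to feature count, scale and
range, with implicit feature selection — but exact C4.5 semantics
(gain-ratio splits, error-based pruning) are not replicated; the
configuration exposes `max_depth`, `min_samples_leaf`, `criterion`
(default entropy) and a split-tie-break `seed` (default 0) instead.
Defaults: unlimited depth with `min_samples_leaf = 20`, so a leaf
aggregates roughly one bag's worth of instances rather than memorising
single windows — a stand-in for pruning.

Leaf class probabilities use add-one (Laplace) smoothing of the leaf's
weighted class counts, p = (w⁺ + 1)/(w + 2), so probabilities never reach
exactly 0 or 1.  This stabilises bag averaging and avoids mass AUC ties
from pure leaves.  A side effect worth knowing: with n identically
featured positive training windows of weight 1/29, the highest reachable
probability is (n/29 + 1)/(n/29 + 2) — about 0.86 at n = 150 — so
high-probability thresholds (e.g. the 0.85 used for the top-7-mer tables)
are only meaningful at sufficient sample size.

### Baseline feature models

All baselines share the same base classifier and configuration surface,
fitted in single-instance mode (one feature vector per probe):

| model | feature vector | length (L = 35) |
|---|---|---|
| SIL3D | positional concatenation of all L−2 triplet rows | 198 |
| k-mer counting | occurrence counts of all 4^k words (overlapping, forward strand, lexicographic A<C<G<T order, raw counts) | 4^k (1024 at k=5, 16384 at k=7) |
| 3+4+5-mer counting | 3-, 4- and 5-mer count vectors concatenated | 1344 |

SIL3D is position-sensitive by construction (its implicit assumption —
that the same position contributes identically across probes — is wrong
for position-independent binding, and it scores worst in every benchmark
here, consistent with expectation).  Counting is position-free but purely
lexical.

## Evaluation

* **AUC** — Mann–Whitney formulation (ties count ½), via
  `sklearn.metrics.roc_auc_score`; unit tests verify exact agreement with
  the O(n²) pairwise oracle.
* **Top high-probability k-mers** — among positive test bags, instances
  with predicted probability ≥ 0.85 (inclusive; sources differ between
  "> 0.85" and "at least 0.85", and ≥ is used here, configurable) are
  pooled, k-mer occurrences counted per qualifying instance (no per-probe
  deduplication), and the top 10 reported with their total.  A few
  dominating k-mers with a high total indicate a strong consensus motif.
* **Cross-TF analyses** — with ≥ 3 TF datasets the benchmark reports
  Pearson correlations (two-sided t-distribution p-values) of the
  MIL-over-counting AUC gain with (a) the top-k-mer total and (b) mean GC
  content of positive test probes (the aggregation over positive test
  probes is a documented choice; other aggregations are defensible), and
  a two-sided paired t-test between the two models' per-TF AUCs.
  Identical AUC lists return (t = 0, p = 1); constant nonzero differences
  are degenerate and raise.
* **Localization** — a positive bag counts as recovered when its
  top-scoring window overlaps the planted site by at least a majority of
  the window ((k+1)//2 bases).  Exact-offset equality is deliberately not
  used: windows overlapping a site are themselves partial sites and
  frequently tie the full-site window's smoothed leaf probability
  exactly, which would make an argmax-equality metric depend on tie
  order.

## Structural-parameter table

The MD-derived table is an external input (TSV, header
`kmer shear buckle stretch propeller stagger opening`, 64 rows).  The
package ships a **placeholder**: fixed-seed pseudo-random values in
plausible physical ranges (translational parameters ~0.15–0.3 units s.d.,
rotational ~3–6° s.d.).  It is not measurement data; it makes the
pipeline runnable and the tests value-agnostic, and any real table in the
same format drops in via `load_structural_table`.  No reverse-complement
symmetrisation is applied to the table or the windows (an
`--add-revcomp` bag option exists, off by default); whether the original
parameter sets averaged a triplet with its reverse complement is not
resolvable here and is left to the supplied table.

## Synthetic data generator

The generator emulates only what the pipeline consumes: probe tables with
signals whose ranking separates motif-carrying probes from background.

* Background bases are i.i.d. with configurable GC fraction (default 0.5,
  matching the near-uniform composition of de Bruijn–style array
  designs).
* Each positive probe receives the consensus motif (default `TGACGTC`,
  7 bp — a common motif-core length) at a uniform random recorded offset,
  with optional per-base mutation; signal = base + 2.0 × (site present) +
  N(0, 0.3), so top/bottom labelling recovers the planted classes almost
  perfectly while leaving rank noise.
* All randomness flows through named substreams (background, insert,
  offsets, mutations, noise, variant) of a single seed: outputs are
  byte-reproducible and new features never perturb existing streams.

**Weak-consensus mode** (`motif_mode="structural_neighborhood"`): instead
of one consensus, each positive receives one of the n (default 16)
*word-disjoint structural neighbours* of the motif — same-length
sequences closest to the motif in structural-vector space, picked
greedily under the constraint that no variant shares an aligned 5-mer
with the motif or with any other variant.  This is the n-variant
generalisation of the single structural twin
(`structural_twin_motif`, exhaustive for length ≤ 7, greedy
single-substitution beyond, lexicographic tie-breaks).  The constraint
matters: without it, nearest structural neighbours share exact triplets
with the motif and hence 5-mer words, and a counting model inherits the
signal.  With it, counting has no reliable word (its AUC falls toward
~0.6 at these sizes) while the structural MIL model retains ~0.75 —
the regime where structural similarity carries information that sequence
identity does not.

What the generator does **not** emulate: array replicate structure,
spatial effects, de Bruijn coverage, realistic intensity distributions
(signals are arbitrary reals; only their ranking enters the pipeline),
and — most importantly — a *measured* structure–sequence relationship,
since the placeholder table is synthetic.  Passing tests therefore
demonstrate correctness of the machinery and the qualitative
MIL-vs-counting behaviour under the stated generative assumptions, not
performance on real PBM data.

## Problem sizes and numerics

Test-suite and acceptance runs use 150 probes per class per array (300
bags of 29 instances each at k = 7) and 5 replicates — sizes at which
every reported effect (MIL AUC > 0.9 on consensus data, localization
≥ 0.8, weak-consensus gain over counting) is stable across seed choices.
Bag weights sum to 1 within 1e-12; bag probabilities equal a per-instance
brute-force mean within 1e-12; selection ties (labelling cuts, top-k-mer
ranks, twin search) all break deterministically (probe id, lexicographic
k-mer) so every run is reproducible bit-for-bit given its seeds.

## Known limitations

* The placeholder table carries no real structural information; all
  quantitative results on synthetic data are properties of the pipeline,
  not of DNA.
* The base tree is CART, not C4.5; probability estimates and split
  choices differ from WEKA's J48 even on identical data.
* Forward strand only by default; palindromic or strand-ambiguous motifs
  are only represented if the supplied data includes them.
* The wrapper MIL bag score dilutes a single strong instance by the bag
  size (a lone certain site contributes at most 1/29 above baseline),
  which bounds the bag-level margin on sparse signals.
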