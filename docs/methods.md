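# Methods

## Problem and model

`pephgc` addresses multi-label association of ncRNA-encoded peptides (ncPEPs)
with cancer types. The biological prior is that peptides translated from the
same non-coding transcript share a transcriptional origin, and that origin is
informative about disease association. The data model is a hypergraph: each
peptide is a vertex, each transcript is a hyperedge containing every peptide
it encodes, and the same peptide may belong to many hyperedges (many-to-many
translation).

Let H be the N×M binary incidence matrix, Dv and De the diagonal vertex and
hyperedge degree matrices, W a diagonal matrix of positive hyperedge weights
and Θ a trainable linear map. One hypergraph convolution layer performs two
phases:

* vertex → hyperedge: Y = W De⁻¹ Hᵀ X (each hyperedge takes the weighted
  mean of its members' features),
* hyperedge → vertex: X′ = σ(Dv⁻¹ H Y Θ + b) (each vertex averages the
  features of its hyperedges).

With b = 0 the composition is the single matrix expression
σ(Dv⁻¹ H W De⁻¹ Hᵀ X Θ). For W = 1 the linear part is row-stochastic on
covered vertices, so constant feature vectors are fixed points — a property
the tests assert exactly. Two comparison operators are provided: the
symmetric-normalized variant σ(Dv^{-1/2} H W De⁻¹ Hᵀ Dv^{-1/2} X Θ), and an
ordinary graph convolution σ(D̃^{-1/2}(A+I)D̃^{-1/2} X Θ) run on the clique
expansion of the hypergraph (every hyperedge replaced by a clique).

Vertex features come from a multi-width convolutional sequence encoder
(token embedding → parallel 1-D convolutions → rectifier → max over full
windows → concatenation). The classifier fuses raw and propagated features
(concatenation by default) and emits one sigmoid score per cancer type, so
the task is a bank of per-label binary problems rather than one softmax.

## Numerical engine

All differentiable components run on a small in-package reverse-mode
autodiff engine over NumPy arrays (tape of closures, iterative topological
backward pass). The engine implements exactly the operations the models
need; its gradients are validated against central finite differences to
~1e-6 in the test suite. The hypergraph/graph propagation operators are
constant `scipy.sparse` matrices; only Hᵀ-free products with them enter the
tape (gradient Pᵀg). Optimization is full-batch adaptive-moment descent
(Adam, β = 0.9/0.999).

## Training protocol

Training is transductive: every forward pass covers all vertices (hyperedges
span the data splits), and the loss is restricted to training rows, so
gradients with respect to held-out rows are exactly zero (asserted in the
tests by perturbing a held-out label). Data are split 80/10/10 with floored
validation/test sizes (4019 peptides → 3217/401/401). After every epoch the
validation macro AUC is recorded; the parameter state that maximizes it is
retained (identified by a content hash) and the test split is scored once,
on that state only. Early stopping uses a patience counter on the selection
metric.

Four losses are available for the imbalanced multi-label setting: per-cell
binary cross-entropy, the same with inverse-frequency class weights
N/(C·count_c), focal loss −(1−p)^γ log p (γ ≥ 0; γ = 0 reduces exactly to
cross-entropy), and online hard-example mining, which ranks per-peptide
(row-mean) losses and averages the top max(1, ⌊keep·n⌋). Hardness is ranked
per peptide, not per cell, because a "hard example" is an example.

## Metrics

Per-class AUC uses the rank (Mann-Whitney) definition with average ranks, so
ties count half; classes with a single-valued label column in a split are
excluded from the macro average with a warning. ACC, precision, recall and
MCC are computed per class from thresholded confusion counts (threshold 0.5
by default) and macro-averaged; MCC with a zero denominator factor is
defined as 0. A per-cell accuracy is reported alongside macro ACC because
sparse multi-label targets make plain accuracy dominated by true negatives.

## Synthetic benchmark

The generator emits the exact TSV/FASTA dialects the parsers read, at the
scale of the curated benchmark (defaults: 4019 peptides, 3066 transcripts,
15 classes, geometric class imbalance of roughly 10:1 across 15 classes).
Hyperedge sizes are shifted negative-binomial (Gamma-Poisson, minimum 1)
with mean 2.0 and dispersion 1.0 by default; every peptide is guaranteed at
least one transcript. Signal modes:

* **hyperedge** — each transcript draws `labels_per_transcript` (default 2)
  classes by the imbalance weights; a peptide's labels are the union over
  its transcripts; sequences are uniform random residues. Only structure is
  informative.
* **sequence** — labels are drawn per peptide; each class plants a distinct
  length-5 motif into its positive peptides with probability
  `motif_strength`; membership is random and label-independent (verified by
  a permutation test). Only sequence is informative.
* **mixed** — hyperedge-driven labels plus motif planting.

Label noise (off by default) flips each (peptide, class) cell independently;
a row flipped to empty gets one of its original labels restored so every
peptide keeps at least one label. Sequence lengths are uniform on [10, 50].

What the generator does *not* emulate: real amino-acid composition, the
co-occurrence structure of cancer labels in curated databases, and
detectability biases of mass spectrometry. Passing benchmarks here therefore
demonstrate that the pipeline recovers planted transcriptional or motif
signal, not that it reproduces performance on any curated dataset.

## Benchmark problem sizes and known limits

The stochastic benchmarks run at 2000 peptides / 600 transcripts / 8
classes, a scale chosen so a full experiment (two models, three seeds)
completes in minutes on one CPU; hyperedge-signal runs truncate sequences at
20 residues since sequences carry no class signal there. The model
configuration for these runs is a deliberately small encoder (16-dim
embedding, widths 3 and 5, 64 filters per width), one convolution layer,
a 128-unit head, batch-feature standardization on, learning rate 1e-2.

A structural limit of the hyperedge benchmark is worth stating plainly.
With 5% independent cell-flip noise, evaluation is against noisy labels, so
even an oracle that recovers the planted unions perfectly cannot exceed
roughly 0.94 test macro AUC at these settings, and a one-hop
label-propagation oracle (the best vertex-level averaging decoder, computed
directly from the incidence matrix and training labels) reaches about 0.87.
The trained network approaches but does not exceed that averaging ceiling
(typically 0.84–0.86 versus ≈0.50 for the sequence-only ablation). The
hypergraph-benefit effect is therefore large and unambiguous, while any
fixed absolute target above the averaging ceiling is not attainable under
these noise conditions — the benchmark reports what the oracle analysis
shows is recoverable.

## Design choices where the design was open

* Vocabulary order is lexicographic; split rounding floors val/test.
* Records that lose all labels under class filtering are dropped.
* Unknown residues map to 'X' rather than erroring.
* Hyperedge weights default to uniform; a frequency mode (transcript
  incidence counts normalized to mean 1) is provided because the frequency
  table exists in the data model, but nothing establishes it as the better
  prior.
* Isolated peptides stay in the graph with a zero aggregation term (their
  score falls back to sequence features); an optional flag gives each a
  singleton self-hyperedge instead.
* The encoder masks pooling windows that extend past the true sequence end,
  so padding can never leak through the max (a sequence shorter than a
  kernel keeps its single partial window to stay defined).
* Batch-feature standardization between encoder and convolution is off by
  default and on in the benchmark configuration, where it markedly improves
  full-batch conditioning.
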