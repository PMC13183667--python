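# pephgc

Hypergraph-enhanced multi-label classification of ncRNA-encoded peptides
(ncPEPs). Peptides translated from short open reading frames in "non-coding"
RNAs are emerging cancer biomarkers, and most predictors look only at the
amino-acid sequence. `pephgc` models the shared transcriptional origin of
peptides explicitly: every peptide is a vertex, every ncRNA transcript is a
hyperedge over the peptides it encodes, and a hypergraph convolution
enriches each peptide's sequence features with the features of its
transcriptional neighbourhood before a multi-label cancer-type classifier.

The package is aimed at computational biologists who want to (a) run the
full pipeline on a peptide table + peptide→transcript map of their own, or
(b) study when and why transcriptional context helps, using the built-in
synthetic benchmark generator with controllable planted signal.

## Model

With incidence matrix `H` (N peptides × M transcripts), degree matrices
`Dv`, `De`, hyperedge weights `W` and trainable map `Θ`, one convolution
layer computes

    Y      = W · De⁻¹ · Hᵀ · X          (vertex → hyperedge: member mean)
    X_next = σ(Dv⁻¹ · H · Y · Θ + b)    (hyperedge → vertex: edge mean)

which for `b = 0` equals `σ(Dv⁻¹ H W De⁻¹ Hᵀ X Θ)`. A symmetric-normalized
variant (`Dv^{-1/2} … Dv^{-1/2}`) and an ordinary graph convolution on the
clique expansion are included for comparison. Vertex features come from a
multi-width convolutional sequence encoder (TextCNN); training is
transductive full-graph optimization with the loss masked to training rows,
model selection on validation macro AUC, and a single test-set evaluation of
the selected checkpoint. Four imbalance-aware losses are available
(cross-entropy, class-weighted cross-entropy, focal, online hard-example
mining), and evaluation reports per-class rank AUC plus macro ACC/MCC/
precision/recall. Everything differentiable runs on a compact NumPy
autodiff engine shipped with the package (finite-difference-verified).

## Worked example

The two-phase convolution on a 3-peptide toy (transcripts r0={p0,p1},
r1={p1,p2}; identity features/weights; `examples/02_hypergraph_algebra.py`):

```
H =
 [[1. 0.]
 [1. 1.]
 [0. 1.]]
vertex degrees Dv = [1. 2. 1.]  hyperedge degrees De = [2. 2.]

hyperedge features Y = W De^-1 H^T X =
 [[0.5 0.5 0. ]
 [0.  0.5 0.5]]

updated vertex features X' = Dv^-1 H Y =
 [[0.5  0.5  0.  ]
 [0.25 0.5  0.25]
 [0.   0.5  0.5 ]]
```

Row p1 is `[0.25, 0.5, 0.25]`: p1 averages its two transcripts, each of
which averaged two member peptides — transcriptional context blended into
every peptide's representation.

The planted-signal comparison (`examples/03_hypergraph_benefit.py`, 600
peptides whose labels are unions of their transcripts' cancer-type profiles
while sequences are random):

```
conv=hgnnp  best epoch 136  val macro AUC 0.848  test macro AUC 0.855
conv=none   best epoch  15  val macro AUC 0.546  test macro AUC 0.456
```

The hypergraph model ranks held-out peptide–cancer associations far above
chance; the sequence-only ablation cannot beat a coin flip because the
class signal is purely structural here. Exporting post-convolution
embeddings on a similar dataset (`examples/05_embeddings.py`) shows the
same structure geometrically:

```
mean distance within a label combination:  2.802
mean distance between label combinations:  4.277
separation gap (positive = clustered):     0.345
```

## Command line

```sh
pephgc simulate    --config run.yaml --seed 1 --out-dir data/
pephgc build-graph --config run.yaml --seed 1 --out-dir out/
pephgc train       --config run.yaml --seed 1 --out-dir out/
pephgc evaluate    --config run.yaml --seed 1 --out-dir out/ --checkpoint out/checkpoint.npz
pephgc embed       --config run.yaml --seed 1 --out-dir out/ --checkpoint out/checkpoint.npz
```

The YAML schema (data paths, simulation, model, training sections) is
documented in `src/pephgc/config.py`; `tests/test_cli.py` contains a
complete minimal configuration.

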