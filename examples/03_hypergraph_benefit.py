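"""Hypergraph context versus sequence-only prediction on planted signal.

On hyperedge-driven data the sequences are random, so a sequence-only model
has nothing to learn, while the hypergraph convolution can recover labels
from transcriptional context.  Run time: a couple of minutes on one CPU.
"""

from pephgc import (EncoderConfig, LabelVocabulary, ModelSpec, SimConfig,
                    TrainConfig, assemble_model, build_hypergraph,
                    encode_labels, simulate, split_dataset, train)

cfg = SimConfig(n_peptides=600, n_rnas=180, n_classes=6,
                peptides_per_rna_mean=5.0, signal_mode="hyperedge",
                noise_rate=0.05, seed=7)
ds = simulate(cfg)
vocab = LabelVocabulary.from_records(ds.records)
Y = encode_labels(ds.records, vocab)
hg = build_hypergraph(ds.records, ds.tmap)
splits = split_dataset(len(ds.records), seed=7)
seqs = [r.sequence for r in ds.records]

enc = EncoderConfig(embed_dim=16, kernel_widths=(3, 5), filters_per_width=32,
                    dropout=0.1, max_len=20)
for conv in ("hgnnp", "none"):
    spec = ModelSpec(encoder_config=enc, conv=conv, conv_depth=1,
                     head_hidden=(64,), dropout=0.1, standardize=True)
    model = assemble_model(spec, hg if conv != "none" else None, len(vocab), seed=7)
    res = train(model, seqs, Y, splits,
                TrainConfig(epochs=250, lr=1e-2, patience=60, seed=7),
                class_names=vocab.names)
    print(f"conv={conv:5s}  best epoch {res.best_epoch:3d}  "
          f"val macro AUC {res.val_metrics.macro_auc:.3f}  "
          f"test macro AUC {res.test_metrics.macro_auc:.3f}")
print("\nThe hypergraph model ranks held-out peptide-cancer associations far "
      "above chance; the sequence-only model stays near 0.5 because the "
      "sequences carry no class signal here.")
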