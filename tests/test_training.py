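"""Model assembly and the train/select/evaluate protocol on small instances."""

import numpy as np
import pytest

from pephgc import (EncoderConfig, LabelVocabulary, ModelSpec, SimConfig,
                    TrainConfig, assemble_model, build_hypergraph,
                    encode_labels, simulate, split_dataset, train)
from pephgc.encoder import tokenize_batch
from pephgc.losses import training_loss
from pephgc.training import embedding_separation, export_embeddings


def tiny_enc(**kw):
    return EncoderConfig(embed_dim=kw.pop("embed_dim", 6),
                         kernel_widths=(2, 3), filters_per_width=4,
                         dropout=0.0, max_len=12)


@pytest.fixture(scope="module")
def tiny_data():
    cfg = SimConfig(n_peptides=80, n_rnas=25, n_classes=4,
                    peptides_per_rna_mean=4.0, signal_mode="hyperedge", seed=5)
    ds = simulate(cfg)
    vocab = LabelVocabulary.from_records(ds.records)
    Y = encode_labels(ds.records, vocab)
    hg = build_hypergraph(ds.records, ds.tmap)
    splits = split_dataset(80, seed=5)
    return ds, vocab, Y, hg, splits


class TestAssembly:
    def test_score_shape_without_conv(self, tiny_data):
        ds, vocab, Y, hg, _ = tiny_data
        m = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="none"),
                           None, len(vocab), seed=0)
        S = m.score_sequences([r.sequence for r in ds.records[:3]])
        assert S.shape == (3, len(vocab))
        assert np.all((S > 0) & (S < 1))

    def test_concat_fusion_doubles_head_input(self, tiny_data):
        _, vocab, _, hg, _ = tiny_data
        mc = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp",
                                      fusion="concat"), hg, len(vocab))
        mr = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp",
                                      fusion="replace"), hg, len(vocab))
        assert mc.head[0].Wt.data.shape[0] == 2 * mr.head[0].Wt.data.shape[0]

    def test_identical_seed_identical_parameters(self, tiny_data):
        _, vocab, _, hg, _ = tiny_data
        spec = ModelSpec(encoder_config=tiny_enc(), conv="hgnnp")
        a = assemble_model(spec, hg, len(vocab), seed=3)
        b = assemble_model(spec, hg, len(vocab), seed=3)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_conv_without_hypergraph_errors(self):
        with pytest.raises(ValueError, match="requires a hypergraph"):
            assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp"),
                           None, 4)

    @pytest.mark.parametrize("conv", ["hgnnp", "hgnn", "gcn", "none"])
    def test_all_variants_forward(self, tiny_data, conv):
        ds, vocab, _, hg, _ = tiny_data
        m = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv=conv),
                           hg if conv != "none" else None, len(vocab))
        S = m.score_sequences([r.sequence for r in ds.records])
        assert S.shape == (80, len(vocab))


class TestTrainingProtocol:
    def test_two_runs_same_seed_identical_logs(self, tiny_data):
        ds, vocab, Y, hg, splits = tiny_data
        spec = ModelSpec(encoder_config=tiny_enc(), conv="hgnnp", dropout=0.2)
        tc = TrainConfig(epochs=6, lr=1e-2, patience=10, seed=7)
        seqs = [r.sequence for r in ds.records]
        logs = []
        for _ in range(2):
            m = assemble_model(spec, hg, len(vocab), seed=7)
            logs.append(train(m, seqs, Y, splits, tc).epoch_log)
        assert logs[0] == logs[1]

    def test_selection_integrity(self, tiny_data):
        """Reported test metrics come from the validation-best checkpoint."""
        ds, vocab, Y, hg, splits = tiny_data
        m = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp"),
                           hg, len(vocab), seed=1)
        res = train(m, [r.sequence for r in ds.records], Y, splits,
                    TrainConfig(epochs=6, lr=1e-2, patience=10, seed=1))
        from pephgc.training import _state_hash
        assert res.checkpoint_hash == _state_hash(res.best_state)
        # model currently holds the best checkpoint
        assert res.checkpoint_hash == _state_hash(m.state_dict())
        best = max(res.epoch_log, key=lambda e: e["val_macro_auc"])
        assert res.best_epoch == best["epoch"]

    def test_transductive_masking(self, tiny_data):
        """Perturbing a held-out row's labels leaves the training loss unchanged."""
        ds, vocab, Y, hg, splits = tiny_data
        m = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp"),
                           hg, len(vocab), seed=2)
        tokens, lengths = tokenize_batch([r.sequence for r in ds.records], 12)
        S = m.forward(tokens, lengths)
        base = training_loss("ce", S, Y, splits.train).item()
        Y2 = Y.copy()
        Y2[splits.test[0]] = 1 - Y2[splits.test[0]]
        assert training_loss("ce", S, Y2, splits.train).item() == base

    def test_sequence_signal_learnable_without_conv(self):
        """Sequence-only model on strongly motif-driven labels: val AUC > 0.95."""
        cfg = SimConfig(n_peptides=300, n_rnas=80, n_classes=3,
                        signal_mode="sequence", motif_strength=1.0,
                        extra_label_rate=0.0, class_weights=[1, 1, 1], seed=13)
        ds = simulate(cfg)
        vocab = LabelVocabulary.from_records(ds.records)
        Y = encode_labels(ds.records, vocab)
        splits = split_dataset(300, seed=13)
        enc = EncoderConfig(embed_dim=12, kernel_widths=(5,), filters_per_width=12,
                            dropout=0.0, max_len=50)
        m = assemble_model(ModelSpec(encoder_config=enc, conv="none",
                                     head_hidden=(16,), standardize=True),
                           None, len(vocab), seed=13)
        res = train(m, [r.sequence for r in ds.records], Y, splits,
                    TrainConfig(epochs=50, lr=1e-2, patience=50, seed=13),
                    class_names=vocab.names)
        assert res.val_metrics.macro_auc > 0.95

    def test_nonfinite_loss_aborts(self, tiny_data):
        ds, vocab, Y, hg, splits = tiny_data
        m = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp"),
                           hg, len(vocab), seed=1)
        m.head[-1].b.data[:] = np.nan  # poisoned parameters -> non-finite scores
        with pytest.raises(FloatingPointError):
            train(m, [r.sequence for r in ds.records], Y, splits,
                  TrainConfig(epochs=2, lr=1e-2, patience=5, seed=1))


class TestEmbeddings:
    def test_export_shapes_and_tsv(self, tiny_data, tmp_path):
        ds, vocab, Y, hg, splits = tiny_data
        m = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp",
                                     fusion="concat"), hg, len(vocab), seed=0)
        out = tmp_path / "emb.tsv"
        E = export_embeddings(m, ds.records, layer="post_conv", path=out)
        d = m.encoder.output_dim  # convolved features keep the encoder width
        assert E.shape == (80, d + 2)  # + 2 projection columns
        header = out.read_text().splitlines()[0].split("\t")
        assert header[:2] == ["pid", "labels"] and header[-2:] == ["pc1", "pc2"]

    def test_projection_of_2d_embeddings_preserves_geometry(self):
        """PCA of full-rank 2-D data is a rotation: pairwise distances survive."""
        rng = np.random.default_rng(0)
        E = rng.normal(size=(30, 2))
        from sklearn.decomposition import PCA
        P = PCA(n_components=2).fit_transform(E)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(P), pdist(E), atol=1e-9)

    def test_unknown_layer_errors(self, tiny_data):
        ds, vocab, _, hg, _ = tiny_data
        m = assemble_model(ModelSpec(encoder_config=tiny_enc(), conv="hgnnp"),
                           hg, len(vocab))
        with pytest.raises(ValueError):
            export_embeddings(m, ds.records, layer="logits")

    def test_separation_score_on_constructed_clusters(self):
        E = np.vstack([np.zeros((5, 3)), np.ones((5, 3)) * 10])
        labels = [{"a"}] * 5 + [{"b"}] * 5
        sep = embedding_separation(E, labels)
        assert sep["within"] < sep["between"] and sep["gap"] > 0
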