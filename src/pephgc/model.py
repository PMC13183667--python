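"""Model assembly: sequence encoder → hypergraph convolution → classifier head.

The full forward pass is transductive: every peptide's sequence is encoded,
the convolution stack propagates features over the fixed peptide–transcript
hypergraph (or its clique expansion, or not at all for the sequence-only
ablation), the propagated features are fused with the raw sequence features
(concatenation by default, or replacement), and a small MLP head emits one
sigmoid score per cancer type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .encoder import EncoderConfig, get_encoder, tokenize_batch
from .hyperconv import gcn_propagation, hgnn_propagation, hgnnp_propagation
from .hypergraph import Hypergraph, clique_expand

CONV_VARIANTS = ("hgnnp", "hgnn", "gcn", "none")
FUSION_MODES = ("concat", "replace")


@dataclass
class ModelSpec:
    """Architecture description: encoder, conv variant/depth, head, loss."""

    encoder: str = "textcnn"
    encoder_config: EncoderConfig = field(default_factory=EncoderConfig)
    conv: str = "hgnnp"
    conv_depth: int = 2
    head_hidden: tuple[int, ...] = (64,)
    fusion: str = "concat"
    loss: str = "ce"
    loss_params: dict = field(default_factory=dict)
    dropout: float = 0.1
    standardize: bool = False  # batch-wise feature standardization after the encoder

    def __post_init__(self):
        if self.conv not in CONV_VARIANTS:
            raise ValueError(f"unknown conv variant {self.conv!r}; expected {CONV_VARIANTS}")
        if self.fusion not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion!r}; expected {FUSION_MODES}")
        if self.conv_depth < 1:
            raise ValueError("conv_depth must be >= 1")


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.Wt = Tensor(rng.normal(0, scale, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.Wt + self.b

    def params(self):
        return [self.Wt, self.b]


class PeptideClassifier:
    """The assembled network; owns all trainable tensors."""

    def __init__(self, spec: ModelSpec, hg: Hypergraph | None,
                 n_classes: int, seed: int = 0):
        self.spec = spec
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.encoder = get_encoder(spec.encoder)(spec.encoder_config, rng)
        enc_dim = self.encoder.output_dim

        self.P = None
        if spec.conv != "none":
            if hg is None:
                raise ValueError(f"conv={spec.conv!r} requires a hypergraph")
            if hg.N <= 0:
                raise ValueError("hypergraph has no vertices")
            if spec.conv == "hgnnp":
                self.P = hgnnp_propagation(hg)
            elif spec.conv == "hgnn":
                self.P = hgnn_propagation(hg)
            else:
                self.P = gcn_propagation(clique_expand(hg))

        # conv layers keep the encoder width so fusion dimensions stay simple
        self.conv_layers: list[_Linear] = []
        if spec.conv != "none":
            for _ in range(spec.conv_depth):
                self.conv_layers.append(_Linear(enc_dim, enc_dim, rng))

        head_in = enc_dim if spec.conv == "none" or spec.fusion == "replace" \
            else 2 * enc_dim
        self.head: list[_Linear] = []
        dims = [head_in, *spec.head_hidden, n_classes]
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.head.append(_Linear(d_in, d_out, rng))

    def params(self) -> list[Tensor]:
        ps = list(self.encoder.params())
        for layer in self.conv_layers:
            ps += layer.params()
        for layer in self.head:
            ps += layer.params()
        return ps

    def post_step(self) -> None:
        self.encoder.post_step()

    def forward(self, tokens: np.ndarray, lengths: np.ndarray,
                rng: np.random.Generator | None = None,
                training: bool = False, return_embeddings: bool = False):
        """Full-graph forward pass; returns the N×C sigmoid score tensor."""
        enc = self.encoder.forward(tokens, lengths, rng=rng, training=training)
        if self.spec.standardize:
            mu = ag.tmean(enc, axis=0, keepdims=True)
            var = ag.tmean(ag.power(enc - mu, 2.0), axis=0, keepdims=True)
            enc = (enc - mu) * ag.power(var + Tensor(1e-6), -0.5)
        feat = enc
        conv_out = enc
        if self.P is not None:
            h = enc
            for layer in self.conv_layers:
                h = ag.relu(layer(ag.sparse_matmul(self.P, h)))
                if training and rng is not None and self.spec.dropout > 0:
                    keep = 1.0 - self.spec.dropout
                    h = h * Tensor((rng.random(h.shape) < keep) / keep)
            conv_out = h
            feat = h if self.spec.fusion == "replace" else ag.concat([enc, h], axis=1)
        x = feat
        for layer in self.head[:-1]:
            x = ag.relu(layer(x))
        scores = ag.sigmoid(self.head[-1](x))
        if not np.all(np.isfinite(scores.data)):
            raise FloatingPointError("non-finite classifier scores")
        if return_embeddings:
            return scores, {"encoder": enc.data, "post_conv": conv_out.data}
        return scores

    # -- convenience ----------------------------------------------------------
    def score_sequences(self, sequences) -> np.ndarray:
        tokens, lengths = tokenize_batch(sequences, self.spec.encoder_config.max_len)
        return self.forward(tokens, lengths, training=False).data

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            arr = state[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at param_{i}")
            p.data = arr.copy()


def assemble_model(spec: ModelSpec, hg: Hypergraph | None, vocab_size: int,
                   seed: int = 0) -> PeptideClassifier:
    """Build the classifier; dimension mismatches surface here, not mid-forward."""
    return PeptideClassifier(spec, hg, vocab_size, seed=seed)
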