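"""Peptide sequence encoders: tokenizer, TextCNN, and a plugin registry.

The TextCNN maps a padded index vector to a fixed-length embedding: token
embedding lookup (the padding row is frozen at zero), parallel 1-D valid
convolutions of several widths, a rectifier, a max over positions restricted
to windows that touch at least one real residue, and concatenation across
widths.  Because of the global max-pool the output depends only on the
multiset of n-grams present, which makes the architecture a strong
position-independent motif detector for short peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .datasets import ALPHABET

#: residue → token index; A=1 … Y=20 (alphabetical), X=21, 0 reserved for padding
TOKEN_INDEX = {aa: i + 1 for i, aa in enumerate(ALPHABET)}
VOCAB_SIZE = len(ALPHABET) + 1  # + padding row


@dataclass
class TokenizedSequence:
    """Fixed-length token index vector plus the unpadded length."""

    indices: np.ndarray
    true_length: int


@dataclass
class EncoderConfig:
    """TextCNN hyperparameters.

    Defaults are the canonical TextCNN settings; peptides in these datasets
    are short, so ``max_len=50`` covers essentially all of them.
    """

    embed_dim: int = 64
    kernel_widths: tuple[int, ...] = (3, 4, 5)
    filters_per_width: int = 64
    dropout: float = 0.5
    max_len: int = 50

    def __post_init__(self):
        if min(self.embed_dim, self.filters_per_width, self.max_len) <= 0:
            raise ValueError("encoder dimensions must be positive")
        if max(self.kernel_widths) > self.max_len:
            raise ValueError("largest kernel width exceeds max_len")

    @property
    def output_dim(self) -> int:
        return len(self.kernel_widths) * self.filters_per_width


def tokenize(sequence: str, max_len: int) -> TokenizedSequence:
    """Map a sanitized sequence to indices; truncate right, pad right with 0."""
    if not sequence:
        raise ValueError("cannot tokenize an empty sequence")
    idx = np.zeros(max_len, dtype=np.int64)
    clipped = sequence[:max_len]
    for i, aa in enumerate(clipped):
        idx[i] = TOKEN_INDEX[aa]
    return TokenizedSequence(indices=idx, true_length=len(clipped))


def tokenize_batch(sequences, max_len: int) -> tuple[np.ndarray, np.ndarray]:
    toks = [tokenize(s, max_len) for s in sequences]
    return (np.stack([t.indices for t in toks]),
            np.array([t.true_length for t in toks], dtype=np.int64))


class TextCNN:
    """Trainable multi-width convolutional sequence encoder."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        d, F = config.embed_dim, config.filters_per_width
        emb = rng.normal(0, 0.1, size=(VOCAB_SIZE, d))
        emb[0] = 0.0  # padding row stays zero
        self.embedding = Tensor(emb, requires_grad=True)
        self.filters: dict[int, Tensor] = {}
        self.biases: dict[int, Tensor] = {}
        for w in config.kernel_widths:
            scale = np.sqrt(2.0 / (w * d))
            self.filters[w] = Tensor(rng.normal(0, scale, size=(w * d, F)),
                                     requires_grad=True)
            self.biases[w] = Tensor(np.zeros(F), requires_grad=True)

    @property
    def output_dim(self) -> int:
        return self.config.output_dim

    def params(self) -> list[Tensor]:
        return ([self.embedding] + list(self.filters.values())
                + list(self.biases.values()))

    def post_step(self) -> None:
        """Keep the padding embedding frozen at zero after each optimizer update."""
        self.embedding.data[0] = 0.0

    def forward(self, tokens: np.ndarray, lengths: np.ndarray,
                rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        """Encode a batch; returns (N, output_dim).

        Windows extending past the true sequence end are masked to -inf before
        the max (full-window pooling), so extra padding never changes the
        output and the embedding depends only on the sequence's w-grams.
        """
        n, L = tokens.shape
        emb = ag.take(self.embedding, tokens)  # (n, L, d)
        pooled = []
        for w in self.config.kernel_widths:
            P = L - w + 1
            # im2col: stack the w shifted slices along the feature axis
            windows = ag.concat([emb[:, i:P + i, :] for i in range(w)], axis=2)
            flat = ag.reshape(windows, (n * P, w * self.config.embed_dim))
            conv = ag.reshape(flat @ self.filters[w] + self.biases[w],
                              (n, P, self.config.filters_per_width))
            conv = ag.relu(conv)
            # keep only full windows (start+w <= length); a sequence shorter
            # than the kernel keeps its single partial window at position 0
            starts = np.arange(P)[None, :]
            last_full = np.maximum(lengths - w, 0)[:, None]
            invalid = starts > last_full
            mask = np.where(invalid, -1e30, 0.0)[:, :, None]
            pooled.append(ag.max_axis(conv + Tensor(mask), axis=1))
        out = ag.concat(pooled, axis=1)
        if training and rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            dmask = (rng.random(out.shape) < keep) / keep
            out = out * Tensor(dmask)
        return out

    def encode(self, sequences) -> np.ndarray:
        """Convenience inference path: sequences → NumPy embedding matrix."""
        tokens, lengths = tokenize_batch(sequences, self.config.max_len)
        return self.forward(tokens, lengths, training=False).data


class MeanPoolEncoder:
    """Baseline encoder: mean of token embeddings over real positions."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        emb = rng.normal(0, 0.1, size=(VOCAB_SIZE, config.embed_dim))
        emb[0] = 0.0
        self.embedding = Tensor(emb, requires_grad=True)

    @property
    def output_dim(self) -> int:
        return self.config.embed_dim

    def params(self) -> list[Tensor]:
        return [self.embedding]

    def post_step(self) -> None:
        self.embedding.data[0] = 0.0

    def forward(self, tokens, lengths, rng=None, training=False) -> Tensor:
        emb = ag.take(self.embedding, tokens)  # (n, L, d); pad rows are zero
        total = ag.tsum(emb, axis=1)
        return total * Tensor((1.0 / np.maximum(lengths, 1))[:, None])


_ENCODERS: dict[str, type] = {}


def register_encoder(name: str, factory) -> None:
    """Register an encoder factory ``(EncoderConfig, rng) -> encoder``."""
    _ENCODERS[name] = factory


def get_encoder(name: str):
    """Look up a registered encoder factory; unknown names list what exists."""
    if name not in _ENCODERS:
        raise KeyError(f"unknown encoder {name!r}; registered: {sorted(_ENCODERS)}")
    return _ENCODERS[name]


register_encoder("textcnn", TextCNN)
register_encoder("meanpool", MeanPoolEncoder)
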