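"""Train/select/evaluate protocol and embedding export.

Training is transductive full-graph gradient descent: every epoch runs one
forward pass over all peptides, the loss is restricted to the training rows
(so held-out rows contribute exactly zero gradient), and one adaptive-moment
update is applied.  After each epoch the selection metric (validation macro
AUC by default) is recorded; the parameters that maximize it are retained
and the held-out test set is scored once, on that checkpoint only.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .autograd import Adam
from .datasets import SplitIndices
from .encoder import tokenize_batch
from .losses import inverse_frequency_weights, training_loss
from .metrics import MetricsReport, compute_metrics
from .model import PeptideClassifier

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization protocol parameters."""

    epochs: int = 200
    lr: float = 1e-3
    seed: int = 0
    selection_metric: str = "macro_auc"
    patience: int = 30
    threshold: float = 0.5

    def __post_init__(self):
        if self.epochs < 1 or self.lr <= 0 or self.patience < 1:
            raise ValueError("epochs, lr and patience must be positive")


@dataclass
class RunResult:
    """Outcome of one training run."""

    best_state: dict[str, np.ndarray]
    best_epoch: int
    val_metrics: MetricsReport
    test_metrics: MetricsReport
    epoch_log: list[dict] = field(default_factory=list)
    seed: int = 0
    checkpoint_hash: str = ""

    def save_checkpoint(self, path) -> None:
        np.savez(path, **self.best_state)


def _state_hash(state: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(state):
        h.update(key.encode())
        h.update(state[key].tobytes())
    return h.hexdigest()


def train(model: PeptideClassifier, sequences, Y: np.ndarray,
          splits: SplitIndices, cfg: TrainConfig,
          class_names=None) -> RunResult:
    """Run the full protocol; returns metrics from the validation-best checkpoint."""
    Y = np.asarray(Y)
    tokens, lengths = tokenize_batch(sequences, model.spec.encoder_config.max_len)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr)

    loss_params = dict(model.spec.loss_params)
    if model.spec.loss == "ce_weighted" and "class_weights" not in loss_params:
        loss_params["class_weights"] = inverse_frequency_weights(Y[splits.train])

    best_metric = -np.inf
    best_state = model.state_dict()
    best_epoch = -1
    epoch_log: list[dict] = []
    stale = 0

    for epoch in range(cfg.epochs):
        scores = model.forward(tokens, lengths, rng=rng, training=True)
        loss = training_loss(model.spec.loss, scores, Y, splits.train, **loss_params)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.post_step()

        eval_scores = model.forward(tokens, lengths, training=False).data
        val_report = compute_metrics(eval_scores[splits.val], Y[splits.val],
                                     threshold=cfg.threshold, split="val",
                                     class_names=class_names)
        metric = getattr(val_report, cfg.selection_metric)
        epoch_log.append({"epoch": epoch, "train_loss": loss.item(),
                          "val_macro_auc": val_report.macro_auc,
                          "val_mcc": val_report.mcc})
        if metric > best_metric:
            best_metric = metric
            best_state = model.state_dict()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    model.load_state_dict(best_state)
    final_scores = model.forward(tokens, lengths, training=False).data
    val_metrics = compute_metrics(final_scores[splits.val], Y[splits.val],
                                  threshold=cfg.threshold, split="val",
                                  class_names=class_names)
    test_metrics = compute_metrics(final_scores[splits.test], Y[splits.test],
                                   threshold=cfg.threshold, split="test",
                                   class_names=class_names)
    return RunResult(best_state=best_state, best_epoch=best_epoch,
                     val_metrics=val_metrics, test_metrics=test_metrics,
                     epoch_log=epoch_log, seed=cfg.seed,
                     checkpoint_hash=_state_hash(best_state))


def export_embeddings(model: PeptideClassifier, records,
                      layer: str = "post_conv", path=None,
                      add_projection: bool = True) -> np.ndarray:
    """Per-peptide embedding table from the encoder or post-convolution layer.

    Optionally appends a 2-D principal-component projection (the linear
    Euclidean-space view used to inspect class clustering) and writes a TSV
    of pid, labels and coordinates.
    """
    if layer not in ("encoder", "post_conv"):
        raise ValueError(f"unknown layer {layer!r}; expected 'encoder' or 'post_conv'")
    tokens, lengths = tokenize_batch([r.sequence for r in records],
                                     model.spec.encoder_config.max_len)
    _, embs = model.forward(tokens, lengths, training=False, return_embeddings=True)
    E = embs[layer]
    proj = None
    if add_projection:
        from sklearn.decomposition import PCA
        proj = PCA(n_components=2, random_state=0).fit_transform(E)
    if path is not None:
        with open(path, "w") as fh:
            cols = [f"e{i}" for i in range(E.shape[1])]
            if proj is not None:
                cols += ["pc1", "pc2"]
            fh.write("pid\tlabels\t" + "\t".join(cols) + "\n")
            for i, r in enumerate(records):
                row = list(E[i]) + (list(proj[i]) if proj is not None else [])
                fh.write(f"{r.pid}\t{';'.join(sorted(r.labels))}\t"
                         + "\t".join(f"{v:.6g}" for v in row) + "\n")
    return np.hstack([E, proj]) if proj is not None else E


def embedding_separation(E: np.ndarray, label_sets) -> dict[str, float]:
    """Mean within-category vs between-category pairwise distance.

    Categories are distinct label sets (the multi-label combinations used to
    color the Euclidean-space view).  Returns both means and a silhouette-style
    gap score ``(between - within) / max(between, within)``.
    """
    cats = [frozenset(s) for s in label_sets]
    from scipy.spatial.distance import pdist, squareform
    D = squareform(pdist(E))
    n = len(cats)
    same = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            same[i, j] = cats[i] == cats[j]
    iu = np.triu_indices(n, k=1)
    same_u = same[iu]
    d_u = D[iu]
    within = float(d_u[same_u].mean()) if same_u.any() else float("nan")
    between = float(d_u[~same_u].mean()) if (~same_u).any() else float("nan")
    gap = (between - within) / max(between, within)
    return {"within": within, "between": between, "gap": float(gap)}
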