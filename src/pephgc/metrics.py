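"""Evaluation metrics for multi-label cancer-type prediction.

Per-class AUC uses the rank (Mann-Whitney) definition — the probability that
a randomly chosen positive is scored above a randomly chosen negative, with
ties counted half — which is exact under ties and needs no curve
integration.  ACC, precision, recall and MCC are computed per class from the
thresholded confusion counts and macro-averaged; a per-cell accuracy is also
reported because scalar accuracy on sparse multi-label targets is dominated
by true negatives and the two views can diverge sharply.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


def binary_auc(scores, labels) -> float:
    """Rank-based AUC with ties counted ½; requires both classes present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks give exactly half credit to ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_counts(pred, truth) -> tuple[int, int, int, int]:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    return tp, tn, fp, fn


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation; defined as 0 when any denominator factor is 0."""
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return _safe_div(tp * tn - fp * fn, den)


@dataclass
class MetricsReport:
    """Per-class AUC and macro-averaged threshold metrics on one split."""

    split: str
    threshold: float
    per_class_auc: dict[str, float]
    acc: float
    mcc: float
    prec: float
    rec: float
    cell_acc: float
    macro_auc: float = field(init=False)

    def __post_init__(self):
        vals = list(self.per_class_auc.values())
        self.macro_auc = float(np.mean(vals)) if vals else float("nan")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "split": self.split, "threshold": self.threshold,
            "macro_auc": self.macro_auc, "per_class_auc": self.per_class_auc,
            "acc": self.acc, "mcc": self.mcc, "prec": self.prec,
            "rec": self.rec, "cell_acc": self.cell_acc,
        }, indent=2))

    def auc_table_tsv(self, path, Y=None, class_names=None) -> None:
        """TSV table ``class<TAB>auc<TAB>n_pos<TAB>n_neg``."""
        lines = ["class\tauc\tn_pos\tn_neg"]
        for j, (name, auc) in enumerate(self.per_class_auc.items()):
            if Y is not None:
                col = np.asarray(Y)[:, class_names.index(name)]
                n_pos, n_neg = int(col.sum()), int(len(col) - col.sum())
            else:
                n_pos = n_neg = -1
            lines.append(f"{name}\t{auc:.6f}\t{n_pos}\t{n_neg}")
        Path(path).write_text("\n".join(lines) + "\n")


def compute_metrics(S, Y, threshold: float = 0.5, split: str = "test",
                    class_names=None) -> MetricsReport:
    """Score an N×C score matrix against binary targets.

    Classes lacking a positive or a negative in the split are excluded from
    the AUC average with a warning.  Thresholded metrics are macro-averaged
    over all classes; MCC with a zero denominator factor is 0.
    """
    S = np.asarray(S, dtype=float)
    Y = np.asarray(Y)
    if S.shape != Y.shape:
        raise ValueError(f"score/label shape mismatch: {S.shape} vs {Y.shape}")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    n, c = S.shape
    names = list(class_names) if class_names is not None else [f"class{j}" for j in range(c)]

    per_class_auc: dict[str, float] = {}
    for j in range(c):
        try:
            per_class_auc[names[j]] = binary_auc(S[:, j], Y[:, j])
        except ValueError:
            warnings.warn(f"class {names[j]!r}: AUC undefined on split {split!r} "
                          "(single-class column), excluded from the macro average")

    pred = S >= threshold
    accs, mccs, precs, recs = [], [], [], []
    for j in range(c):
        tp, tn, fp, fn = confusion_counts(pred[:, j], Y[:, j])
        accs.append(_safe_div(tp + tn, n))
        mccs.append(mcc_from_counts(tp, tn, fp, fn))
        precs.append(_safe_div(tp, tp + fp))
        recs.append(_safe_div(tp, tp + fn))
    return MetricsReport(
        split=split, threshold=threshold, per_class_auc=per_class_auc,
        acc=float(np.mean(accs)), mcc=float(np.mean(mccs)),
        prec=float(np.mean(precs)), rec=float(np.mean(recs)),
        cell_acc=float((pred == Y.astype(bool)).mean()),
    )
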