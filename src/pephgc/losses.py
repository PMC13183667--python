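"""Imbalance-aware training losses for per-label binary targets.

The classifier emits one sigmoid score per (peptide, cancer type) cell, so
every loss here is an average of per-cell binary cross-entropy style terms:

* ``bce``            — plain cross-entropy, optional per-class weights
* ``focal``          — cross-entropy modulated by (1-p)^γ
* ``ohem``           — mean of the k hardest per-peptide losses only

All losses are differentiable through the autograd engine; the plain-float
entry points simply wrap arrays in constant tensors.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_EPS = 1e-12


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _check_shapes(S, Y):
    if S.shape != np.asarray(Y.data if isinstance(Y, Tensor) else Y).shape:
        raise ValueError(f"score/label shape mismatch: {S.shape} vs {np.shape(Y)}")


def _bce_cells(S: Tensor, Y: np.ndarray) -> Tensor:
    """Per-cell −[y log s + (1−y) log(1−s)] with scores clipped away from {0,1}."""
    # clip in data space; gradient of the clipped region is inexact but the
    # training path never saturates there (sigmoid outputs are interior)
    s = S if S.requires_grad else Tensor(np.clip(S.data, _EPS, 1 - _EPS))
    y = Tensor(np.asarray(Y, dtype=float))
    one = Tensor(1.0)
    return -(y * ag.log(s + Tensor(_EPS)) + (one - y) * ag.log(one - s + Tensor(_EPS)))


def bce_loss_t(S: Tensor, Y, class_weights=None) -> Tensor:
    _check_shapes(S, Y)
    cells = _bce_cells(S, np.asarray(Y))
    if class_weights is not None:
        cells = cells * Tensor(np.asarray(class_weights, dtype=float))
    return ag.tmean(cells)


def focal_loss_t(S: Tensor, Y, gamma: float = 2.0, alpha=None) -> Tensor:
    """Per-cell −α_y (1−p_y)^γ log p_y, p_y = s if y=1 else 1−s; mean over cells."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    _check_shapes(S, Y)
    y = np.asarray(Y, dtype=float)
    s = S if S.requires_grad else Tensor(np.clip(S.data, _EPS, 1 - _EPS))
    one = Tensor(1.0)
    yt = Tensor(y)
    p = yt * s + (one - yt) * (one - s)  # probability assigned to the true cell value
    cells = -(ag.power(one - p, gamma) * ag.log(p + Tensor(_EPS)))
    if alpha is not None:
        a = np.asarray(alpha, dtype=float)
        alpha_y = y * a + (1 - y) * (1 - a) if a.ndim else np.where(y == 1, a, 1 - a)
        cells = cells * Tensor(np.broadcast_to(alpha_y, cells.shape).copy())
    return ag.tmean(cells)


def ohem_loss_t(per_sample_losses: Tensor, keep_ratio: float) -> Tensor:
    """Mean of the k = max(1, floor(keep_ratio·n)) largest per-sample losses."""
    if not 0 < keep_ratio <= 1:
        raise ValueError("keep_ratio must lie in (0, 1]")
    n = per_sample_losses.data.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    k = max(1, int(np.floor(keep_ratio * n)))
    hard = np.argsort(per_sample_losses.data)[::-1][:k].copy()
    return ag.tmean(ag.take(per_sample_losses, hard))


def per_sample_bce_t(S: Tensor, Y, class_weights=None) -> Tensor:
    """Row-wise (per peptide) mean of the weighted BCE cells."""
    cells = _bce_cells(S, np.asarray(Y))
    if class_weights is not None:
        cells = cells * Tensor(np.asarray(class_weights, dtype=float))
    return ag.tmean(cells, axis=1)


# -- plain-float API ----------------------------------------------------------

def bce_loss(S, Y, class_weights=None) -> float:
    """Mean per-cell binary cross-entropy, optionally class-weighted."""
    return bce_loss_t(_as_t(S), Y, class_weights).item()


def focal_loss(S, Y, gamma: float = 2.0, alpha=None) -> float:
    return focal_loss_t(_as_t(S), Y, gamma, alpha).item()


def ohem_loss(per_sample_losses, keep_ratio: float) -> float:
    return ohem_loss_t(_as_t(np.asarray(per_sample_losses, dtype=float)),
                       keep_ratio).item()


def inverse_frequency_weights(Y) -> np.ndarray:
    """Standard inverse-frequency class weights N/(C·count_c)."""
    Y = np.asarray(Y)
    n, c = Y.shape
    counts = np.maximum(Y.sum(axis=0), 1)
    return n / (c * counts)


LOSSES = ("ce", "ce_weighted", "focal", "ohem")


def training_loss(name: str, S: Tensor, Y, mask_rows: np.ndarray,
                  gamma: float = 2.0, keep_ratio: float = 0.7,
                  class_weights=None) -> Tensor:
    """Dispatch a registered loss restricted to the training rows.

    ``mask_rows`` holds the training indices; scores and labels are gathered
    to those rows first, so gradients with respect to held-out rows are
    exactly zero (transductive masking).
    """
    S_tr = ag.take(S, mask_rows)
    Y_tr = np.asarray(Y)[mask_rows]
    if name == "ce":
        return bce_loss_t(S_tr, Y_tr)
    if name == "ce_weighted":
        w = class_weights if class_weights is not None else inverse_frequency_weights(Y_tr)
        return bce_loss_t(S_tr, Y_tr, class_weights=w)
    if name == "focal":
        return focal_loss_t(S_tr, Y_tr, gamma=gamma)
    if name == "ohem":
        return ohem_loss_t(per_sample_bce_t(S_tr, Y_tr), keep_ratio)
    raise KeyError(f"unknown loss {name!r}; registered: {LOSSES}")
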