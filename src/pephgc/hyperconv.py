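"""Hypergraph and graph convolution operators.

The central operator is the two-phase hypergraph convolution (HGNNP):

* vertex→hyperedge:  Y = W De⁻¹ Hᵀ X       (weighted mean of member features)
* hyperedge→vertex:  X' = σ(Dv⁻¹ H Y Θ + b)

whose composition equals the single matrix expression
``σ(Dv⁻¹ H W De⁻¹ Hᵀ X Θ)`` when the bias is zero.  The earlier symmetric
variant (HGNN) normalizes by Dv^{-1/2} on both sides, and the ordinary-graph
baseline (GCN) runs symmetric-normalized propagation with self-loops on the
clique expansion.  Isolated vertices receive a zero aggregation term (their
incidence row is empty), so their output is σ(bias).

Two faces are exposed: plain-NumPy functional ops matching the formulas above
(used directly and as the testing surface), and propagation-matrix builders
shared with the trainable model layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .hypergraph import CliqueGraph, Hypergraph, incidence_and_degrees

_ACTIVATIONS = {
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
    "sigmoid": lambda x: 1.0 / (1.0 + np.exp(-x)),
}


@dataclass
class ConvParams:
    """Weights of one convolution layer: Theta (d_in×d_out), bias, activation."""

    Theta: np.ndarray
    bias: np.ndarray | None = None
    activation: str = "relu"

    def act(self, x: np.ndarray) -> np.ndarray:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        return _ACTIVATIONS[self.activation](x)


def _check_finite(X: np.ndarray, where: str) -> np.ndarray:
    if not np.all(np.isfinite(X)):
        raise FloatingPointError(f"non-finite values in {where} output")
    return X


# -- propagation operators ----------------------------------------------------

def hgnnp_propagation(hg: Hypergraph) -> sp.csr_matrix:
    """P = Dv⁻¹ H W De⁻¹ Hᵀ (row-stochastic for W=1; zero rows for isolated vertices)."""
    H, Dv, De = incidence_and_degrees(hg)
    dv_inv = np.divide(1.0, Dv, out=np.zeros_like(Dv, dtype=float), where=Dv > 0)
    de_inv = 1.0 / De
    P = sp.diags(dv_inv) @ H @ sp.diags(hg.W * de_inv) @ H.T
    return sp.csr_matrix(P)


def hgnn_propagation(hg: Hypergraph) -> sp.csr_matrix:
    """P = Dv^{-1/2} H W De⁻¹ Hᵀ Dv^{-1/2} (symmetric normalization)."""
    H, Dv, De = incidence_and_degrees(hg)
    dv_isqrt = np.divide(1.0, np.sqrt(Dv), out=np.zeros_like(Dv, dtype=float),
                         where=Dv > 0)
    de_inv = 1.0 / De
    P = sp.diags(dv_isqrt) @ H @ sp.diags(hg.W * de_inv) @ H.T @ sp.diags(dv_isqrt)
    return sp.csr_matrix(P)


def gcn_propagation(cg: CliqueGraph) -> sp.csr_matrix:
    """P = D̃^{-1/2}(A+I)D̃^{-1/2} with D̃ the degree of A+I (self-loops added)."""
    A_hat = sp.csr_matrix(cg.A + sp.eye(cg.N))
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_isqrt = 1.0 / np.sqrt(deg)
    return sp.csr_matrix(sp.diags(d_isqrt) @ A_hat @ sp.diags(d_isqrt))


# -- functional layer ops -----------------------------------------------------

def v2e_aggregate(hg: Hypergraph, X: np.ndarray) -> np.ndarray:
    """Hyperedge features Y = W De⁻¹ Hᵀ X: weighted mean of member-vertex features."""
    H, _, De = incidence_and_degrees(hg)
    return sp.diags(hg.W / De) @ H.T @ X


def e2v_update(hg: Hypergraph, Y: np.ndarray, params: ConvParams) -> np.ndarray:
    """Vertex update X' = σ(Dv⁻¹ H Y Θ + b); isolated vertices aggregate zero."""
    H, Dv, _ = incidence_and_degrees(hg)
    dv_inv = np.divide(1.0, Dv, out=np.zeros_like(Dv, dtype=float), where=Dv > 0)
    Z = (sp.diags(dv_inv) @ H @ Y) @ params.Theta
    if params.bias is not None:
        Z = Z + params.bias
    return _check_finite(params.act(Z), "e2v_update")


def hgnnp_layer(X: np.ndarray, hg: Hypergraph, params: ConvParams) -> np.ndarray:
    """Two-phase hypergraph convolution; equals σ(Dv⁻¹HWDe⁻¹HᵀXΘ) at bias 0."""
    return e2v_update(hg, v2e_aggregate(hg, X), params)


def hgnn_layer(X: np.ndarray, hg: Hypergraph, params: ConvParams) -> np.ndarray:
    """Symmetric-normalized hypergraph convolution σ(Dv^{-1/2}HWDe⁻¹HᵀDv^{-1/2}XΘ)."""
    Z = (hgnn_propagation(hg) @ X) @ params.Theta
    if params.bias is not None:
        Z = Z + params.bias
    return _check_finite(params.act(Z), "hgnn_layer")


def gcn_layer(X: np.ndarray, cg: CliqueGraph, params: ConvParams) -> np.ndarray:
    """Graph convolution σ(D̃^{-1/2}(A+I)D̃^{-1/2}XΘ) on the clique expansion."""
    Z = (gcn_propagation(cg) @ X) @ params.Theta
    if params.bias is not None:
        Z = Z + params.bias
    return _check_finite(params.act(Z), "gcn_layer")
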