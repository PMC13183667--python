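"""Convolution operators versus their dense matrix-formula oracles.

Every layer must reproduce its one-shot dense expression on random small
instances — the central correctness property of the propagation algebra.
"""

import numpy as np
import pytest

from pephgc import (ConvParams, clique_expand, e2v_update, gcn_layer,
                    hgnn_layer, hgnnp_layer, incidence_and_degrees,
                    v2e_aggregate)
from pephgc.hypergraph import Hypergraph
from conftest import random_hypergraph

ACTS = {"identity": lambda x: x, "relu": lambda x: np.maximum(x, 0.0)}


def dense_parts(hg):
    H, Dv, De = incidence_and_degrees(hg, sparse=False)
    dv_inv = np.divide(1.0, Dv, out=np.zeros_like(Dv), where=Dv > 0)
    return H, Dv, De, dv_inv


def dense_hgnnp(hg, X, Theta, act):
    H, Dv, De, dv_inv = dense_parts(hg)
    P = np.diag(dv_inv) @ H @ np.diag(hg.W) @ np.diag(1.0 / De) @ H.T
    return ACTS[act](P @ X @ Theta)


def dense_hgnn(hg, X, Theta, act):
    H, Dv, De, _ = dense_parts(hg)
    disq = np.divide(1.0, np.sqrt(Dv), out=np.zeros_like(Dv), where=Dv > 0)
    P = np.diag(disq) @ H @ np.diag(hg.W) @ np.diag(1.0 / De) @ H.T @ np.diag(disq)
    return ACTS[act](P @ X @ Theta)


def dense_gcn(cg, X, Theta, act):
    A_hat = cg.A.toarray() + np.eye(cg.N)
    disq = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return ACTS[act](np.diag(disq) @ A_hat @ np.diag(disq) @ X @ Theta)


class TestWorkedExample:
    """Es=[{0,1},{1,2}], X=I, W=Θ=I, σ=id — every stage hand-checkable."""

    def test_v2e(self, path_hypergraph):
        Y = v2e_aggregate(path_hypergraph, np.eye(3))
        np.testing.assert_allclose(Y, [[0.5, 0.5, 0], [0, 0.5, 0.5]])

    def test_e2v(self, path_hypergraph):
        params = ConvParams(Theta=np.eye(3), activation="identity")
        Y = v2e_aggregate(path_hypergraph, np.eye(3))
        X1 = e2v_update(path_hypergraph, Y, params)
        np.testing.assert_allclose(
            X1, [[0.5, 0.5, 0], [0.25, 0.5, 0.25], [0, 0.5, 0.5]])

    def test_hgnnp_layer_equals_composition(self, path_hypergraph):
        params = ConvParams(Theta=np.eye(3), activation="identity")
        X1 = hgnnp_layer(np.eye(3), path_hypergraph, params)
        np.testing.assert_allclose(
            X1, [[0.5, 0.5, 0], [0.25, 0.5, 0.25], [0, 0.5, 0.5]])


class TestV2E:
    def test_constant_rows_give_constant_edges(self, path_hypergraph):
        X = np.full((3, 4), 3.25)
        Y = v2e_aggregate(path_hypergraph, X)
        np.testing.assert_allclose(Y, np.full((2, 4), 3.25))

    def test_linearity_in_edge_weight(self, path_hypergraph):
        X = np.arange(6.0).reshape(3, 2)
        Y1 = v2e_aggregate(path_hypergraph, X)
        path_hypergraph.W = np.array([2.0, 1.0])
        Y2 = v2e_aggregate(path_hypergraph, X)
        np.testing.assert_allclose(Y2[0], 2 * Y1[0])
        np.testing.assert_allclose(Y2[1], Y1[1])


@pytest.mark.parametrize("act", ["identity", "relu"])
def test_oracle_parity_200_random_instances(act):
    """hgnnp/hgnn/gcn match their dense formulas to 1e-6 on 200 random cases."""
    rng = np.random.default_rng(7)
    worst = 0.0
    for _ in range(200):
        hg = random_hypergraph(rng)
        d_in, d_out = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        X = rng.normal(size=(hg.N, d_in))
        params = ConvParams(Theta=rng.normal(size=(d_in, d_out)), activation=act)
        worst = max(worst,
                    np.abs(hgnnp_layer(X, hg, params) - dense_hgnnp(hg, X, params.Theta, act)).max(),
                    np.abs(hgnn_layer(X, hg, params) - dense_hgnn(hg, X, params.Theta, act)).max())
        cg = clique_expand(hg)
        worst = max(worst,
                    np.abs(gcn_layer(X, cg, params) - dense_gcn(cg, X, params.Theta, act)).max())
    assert worst <= 1e-6


class TestFixedPointAndDegenerate:
    def test_constant_input_preserved(self, rng):
        """The linear HGNNP operator with W=1 is row-stochastic on covered vertices."""
        for _ in range(10):
            hg = random_hypergraph(rng)
            hg.W = np.ones(hg.M)
            c = rng.normal()
            X = np.full((hg.N, 3), c)
            params = ConvParams(Theta=np.eye(3), activation="identity")
            out = hgnnp_layer(X, hg, params)
            _, Dv, _ = incidence_and_degrees(hg)
            np.testing.assert_allclose(out[Dv > 0], c, atol=1e-12)

    def test_isolated_vertex_outputs_bias(self):
        hg = Hypergraph(N=3, Es=[{0, 1}])
        bias = np.array([0.7, -0.2])
        params = ConvParams(Theta=np.ones((2, 2)), bias=bias, activation="identity")
        out = hgnnp_layer(np.ones((3, 2)), hg, params)
        np.testing.assert_allclose(out[2], bias)

    def test_zero_theta_gives_activated_bias(self, path_hypergraph):
        params = ConvParams(Theta=np.zeros((3, 2)), bias=np.array([-1.0, 2.0]),
                            activation="relu")
        out = hgnnp_layer(np.random.default_rng(0).normal(size=(3, 3)),
                          path_hypergraph, params)
        np.testing.assert_allclose(out, np.tile([0.0, 2.0], (3, 1)))

    def test_zero_input_hgnn(self, path_hypergraph):
        params = ConvParams(Theta=np.eye(3), activation="relu")
        out = hgnn_layer(np.zeros((3, 3)), path_hypergraph, params)
        np.testing.assert_allclose(out, 0.0)

    def test_regular_hypergraph_hgnn_vs_hgnnp_scalar_ratio(self):
        """On a 2-regular structure the two normalizations agree up to a scalar."""
        hg = Hypergraph(N=4, Es=[{0, 1}, {1, 2}, {2, 3}, {3, 0}])  # Dv=2, De=2
        X = np.random.default_rng(1).normal(size=(4, 3))
        params = ConvParams(Theta=np.eye(3), activation="identity")
        a, b = hgnnp_layer(X, hg, params), hgnn_layer(X, hg, params)
        ratio = b[np.abs(a) > 1e-9] / a[np.abs(a) > 1e-9]
        np.testing.assert_allclose(ratio, ratio.flat[0])
        assert ratio.flat[0] > 0

    def test_nan_guard(self, path_hypergraph):
        params = ConvParams(Theta=np.array([[np.inf] * 3] * 3), activation="identity")
        with pytest.raises(FloatingPointError):
            hgnnp_layer(np.ones((3, 3)), path_hypergraph, params)


class TestGCN:
    def test_single_vertex_self_loop_only(self):
        hg = Hypergraph(N=1, Es=[{0}])
        cg = clique_expand(hg)  # no edges
        X = np.array([[2.0, -1.0]])
        params = ConvParams(Theta=np.eye(2), activation="identity")
        np.testing.assert_allclose(gcn_layer(X, cg, params), X)

    def test_k3_symmetry(self):
        cg = clique_expand(Hypergraph(N=3, Es=[{0, 1, 2}]))
        X = np.tile([1.0, 2.0], (3, 1))
        params = ConvParams(Theta=np.eye(2), activation="identity")
        out = gcn_layer(X, cg, params)
        np.testing.assert_allclose(out, np.tile(out[0], (3, 1)))


def test_permutation_equivariance(rng):
    """Relabeling vertices permutes the layer output identically."""
    for _ in range(5):
        hg = random_hypergraph(rng)
        X = rng.normal(size=(hg.N, 4))
        params = ConvParams(Theta=rng.normal(size=(4, 3)), activation="relu")
        perm = rng.permutation(hg.N)
        inv = np.argsort(perm)
        hg_p = Hypergraph(N=hg.N, Es=[frozenset(int(inv[v]) for v in e) for e in hg.Es],
                          W=hg.W)
        out = hgnnp_layer(X, hg, params)
        out_p = hgnnp_layer(X[perm], hg_p, params)  # new vertex j = old vertex perm[j]
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_locality(rng):
    """Zeroing features outside one hyperedge leaves non-neighbors at σ(bias)."""
    hg = Hypergraph(N=6, Es=[{0, 1}, {2, 3}, {4, 5}])
    X = np.zeros((6, 2))
    X[0] = X[1] = [1.0, -2.0]
    params = ConvParams(Theta=np.eye(2), bias=np.array([0.5, 0.5]), activation="relu")
    out = hgnnp_layer(X, hg, params)
    for v in (2, 3, 4, 5):
        np.testing.assert_allclose(out[v], [0.5, 0.5])
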