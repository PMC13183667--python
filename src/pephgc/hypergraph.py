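"""Peptide–transcript hypergraph: incidence algebra and clique expansion.

Vertices are peptides (indexed by their position in the record list) and each
transcript is one hyperedge containing every peptide it encodes.  A peptide
translated from several transcripts belongs to several hyperedges, so the
structure is genuinely many-to-many.  The incidence matrix H (N×M, binary),
the vertex/hyperedge degree vectors Dv/De and the hyperedge weight vector W
are everything the convolution operators downstream need.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .datasets import TranscriptMap

logger = logging.getLogger(__name__)


@dataclass
class Hypergraph:
    """A hypergraph over N vertices with M hyperedges (vertex-index sets)."""

    N: int
    Es: list[frozenset[int]]
    edge_ids: list[str] = field(default_factory=list)
    W: np.ndarray = None
    frequencies: np.ndarray = None  # per-edge transcript incidence counts

    def __post_init__(self):
        if not self.edge_ids:
            self.edge_ids = [f"e{i}" for i in range(len(self.Es))]
        self.Es = [frozenset(e) for e in self.Es]
        for e in self.Es:
            if not e:
                raise ValueError("empty hyperedge")
            if max(e) >= self.N or min(e) < 0:
                raise ValueError("hyperedge vertex index out of range")
        if self.W is None:
            self.W = np.ones(len(self.Es))
        self.W = np.asarray(self.W, dtype=float)

    @property
    def M(self) -> int:
        return len(self.Es)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "N": self.N,
            "edge_ids": self.edge_ids,
            "Es": [sorted(e) for e in self.Es],
            "W": self.W.tolist(),
        }))

    @classmethod
    def from_json(cls, path) -> "Hypergraph":
        d = json.loads(Path(path).read_text())
        return cls(N=d["N"], Es=[frozenset(e) for e in d["Es"]],
                   edge_ids=list(d["edge_ids"]), W=np.asarray(d["W"]))

    def write_incidence_coo(self, path) -> None:
        """Plain-text coordinate export: one ``row col 1`` line per incidence."""
        with open(path, "w") as fh:
            for j, e in enumerate(self.Es):
                for v in sorted(e):
                    fh.write(f"{v} {j} 1\n")


@dataclass
class CliqueGraph:
    """Ordinary graph obtained by replacing each hyperedge with a clique."""

    N: int
    A: sp.csr_matrix  # symmetric binary, zero diagonal


def build_hypergraph(records, tmap: TranscriptMap,
                     add_self_edges_for_isolated: bool = False) -> Hypergraph:
    """Construct the hypergraph: one hyperedge per distinct transcript.

    Vertex index = position of the pid in ``records``.  Hyperedge order is the
    first-appearance order of each rid in the membership table.  Duplicate
    (pid, rid) pairs collapse to a single incidence.  Peptides with no
    transcript become isolated vertices unless ``add_self_edges_for_isolated``
    gives each of them a singleton self-hyperedge.
    """
    pid_to_idx = {r.pid: i for i, r in enumerate(records)}
    members: dict[str, set[int]] = {}
    order: list[str] = []
    for pid, rids in tmap.membership.items():
        if pid not in pid_to_idx:
            continue
        v = pid_to_idx[pid]
        for rid in rids:
            if rid not in members:
                members[rid] = set()
                order.append(rid)
            members[rid].add(v)

    Es: list[frozenset[int]] = []
    edge_ids: list[str] = []
    freqs: list[int] = []
    for rid in order:
        if not members[rid]:
            logger.warning("transcript %s: no surviving members, hyperedge dropped", rid)
            continue
        Es.append(frozenset(members[rid]))
        edge_ids.append(rid)
        freqs.append(tmap.frequency.get(rid, len(members[rid])))

    if add_self_edges_for_isolated:
        covered = set().union(*Es) if Es else set()
        for v in range(len(records)):
            if v not in covered:
                Es.append(frozenset({v}))
                edge_ids.append(f"self:{records[v].pid}")
                freqs.append(1)

    hg = Hypergraph(N=len(records), Es=Es, edge_ids=edge_ids)
    hg.frequencies = np.asarray(freqs, dtype=float)
    return hg


def incidence_and_degrees(hg: Hypergraph, sparse: bool = True):
    """Incidence matrix H plus vertex/hyperedge degrees recomputed from it."""
    rows, cols = [], []
    for j, e in enumerate(hg.Es):
        for v in e:
            rows.append(v)
            cols.append(j)
    H = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(hg.N, hg.M))
    if not sparse:
        H = H.toarray()
        Dv = H.sum(axis=1)
        De = H.sum(axis=0)
    else:
        Dv = np.asarray(H.sum(axis=1)).ravel()
        De = np.asarray(H.sum(axis=0)).ravel()
    return H, Dv, De


def set_edge_weights(hg: Hypergraph, mode: str = "uniform") -> Hypergraph:
    """Set hyperedge weights: all-ones, or transcript frequencies scaled to mean 1."""
    if mode == "uniform":
        hg.W = np.ones(hg.M)
    elif mode == "frequency":
        if hg.frequencies is None or len(hg.frequencies) != hg.M:
            raise ValueError("frequency mode requires transcript frequencies on the hypergraph")
        f = np.asarray(hg.frequencies, dtype=float)
        hg.W = f / f.mean()
    else:
        raise ValueError(f"unknown weight mode {mode!r}; expected 'uniform' or 'frequency'")
    return hg


def clique_expand(hg: Hypergraph) -> CliqueGraph:
    """Replace each hyperedge by a clique over its members (no self-loops)."""
    rows, cols = [], []
    for e in hg.Es:
        mem = sorted(e)
        for i, u in enumerate(mem):
            for v in mem[i + 1:]:
                rows += [u, v]
                cols += [v, u]
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(hg.N, hg.N))
    A.data[:] = 1.0  # binary: multiple shared hyperedges still one edge
    A.setdiag(0)
    A.eliminate_zeros()
    return CliqueGraph(N=hg.N, A=A)
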