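import numpy as np
import pytest

from pephgc import PeptideRecord, TranscriptMap
from pephgc.hypergraph import Hypergraph


@pytest.fixture
def toy_records():
    return [
        PeptideRecord("p0", "MKV", frozenset({"colon cancer"})),
        PeptideRecord("p1", "ACDEF", frozenset({"colon cancer", "lung cancer"})),
        PeptideRecord("p2", "GHIKL", frozenset({"lung cancer"})),
    ]


@pytest.fixture
def toy_tmap():
    return TranscriptMap({"p0": ["r0"], "p1": ["r0", "r1"], "p2": ["r1"]})


@pytest.fixture
def path_hypergraph():
    """Es=[{0,1},{1,2}]: the worked 3-vertex example."""
    return Hypergraph(N=3, Es=[{0, 1}, {1, 2}])


def random_hypergraph(rng, n_max=20, m_max=10):
    """Random small hypergraph with at least one non-empty hyperedge."""
    n = int(rng.integers(2, n_max + 1))
    m = int(rng.integers(1, m_max + 1))
    Es = []
    for _ in range(m):
        size = int(rng.integers(1, n + 1))
        Es.append(frozenset(rng.choice(n, size=size, replace=False).tolist()))
    W = rng.uniform(0.2, 2.0, size=m)
    return Hypergraph(N=n, Es=Es, W=W)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
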