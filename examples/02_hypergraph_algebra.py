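"""The two-phase hypergraph convolution on a worked 3-peptide example.

Two transcripts r0={p0,p1} and r1={p1,p2} give the incidence matrix
H=[[1,0],[1,1],[0,1]].  With identity features, unit weights and an identity
transform, the vertex->edge stage averages member features and the
edge->vertex stage averages edge features, so every number below is
hand-checkable.
"""

import numpy as np

from pephgc import (ConvParams, PeptideRecord, TranscriptMap, build_hypergraph,
                    hgnnp_layer, incidence_and_degrees, v2e_aggregate)

records = [PeptideRecord(p, s, frozenset({"colon cancer"}))
           for p, s in [("p0", "MKV"), ("p1", "ACDEF"), ("p2", "GHIKL")]]
tmap = TranscriptMap({"p0": ["r0"], "p1": ["r0", "r1"], "p2": ["r1"]})
hg = build_hypergraph(records, tmap)

H, Dv, De = incidence_and_degrees(hg, sparse=False)
print("H =\n", H)
print("vertex degrees Dv =", Dv, " hyperedge degrees De =", De)

X = np.eye(3)
Y = v2e_aggregate(hg, X)
print("\nhyperedge features Y = W De^-1 H^T X =\n", Y)

params = ConvParams(Theta=np.eye(3), activation="identity")
X1 = hgnnp_layer(X, hg, params)
print("\nupdated vertex features X' = Dv^-1 H Y =\n", X1)
print("\nRow p1 is [0.25, 0.5, 0.25]: it averages both transcripts' features, "
      "each of which averaged two member peptides.")
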