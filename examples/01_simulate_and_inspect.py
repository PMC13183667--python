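"""Generate a small synthetic peptide/transcript dataset and inspect it.

The generator emits the same TSV/FASTA dialect the parsers read.  In
hyperedge mode each transcript carries a sparse cancer-type profile and a
peptide's labels are the union of its transcripts' profiles, so class
structure lives in the hypergraph rather than in the sequences.
"""

import json
from pathlib import Path

from pephgc import SimConfig, generate, parse_peptides, parse_transcript_map, summarize

out = Path("example_out/sim")
paths = generate(SimConfig(n_peptides=300, n_rnas=90, n_classes=6,
                           peptides_per_rna_mean=4.0, signal_mode="hyperedge",
                           noise_rate=0.05, seed=1), out)
records = parse_peptides(paths["peptides_tsv"], paths["peptides_fasta"])
tmap = parse_transcript_map(paths["transcript_map"], records)

summary = summarize(records, tmap)
print(json.dumps(summary, indent=2))
print(f"\n{summary['n_peptides']} peptides over {summary['n_transcripts']} transcripts; "
      f"mean label cardinality {summary['mean_label_cardinality']:.2f} "
      "(peptides inherit every cancer type of every transcript that encodes them).")
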