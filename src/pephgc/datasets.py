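"""Peptide tables, transcript maps, label vocabularies and dataset splits.

The input contract is deliberately small: a peptide table (TSV with columns
``pid``, ``sequence``, ``labels``; labels semicolon-separated, sequence
optionally supplied by a companion FASTA keyed on pid) and a peptide→transcript
map (TSV with columns ``pid``, ``rids``; rids semicolon-separated).  These two
files fully determine the multi-label targets and the peptide–transcript
hypergraph downstream.

Cancer-type vocabularies are ordered lexicographically so that label-matrix
columns are stable across runs and machines.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids plus 'X' for unknown/nonstandard residues.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

LABEL_DELIM = ";"

#: Cancer types of the curated ncPEP benchmark (15-class setting).
CANCER_TYPES_15 = (
    "anal canal cancer", "bile duct cancer", "bladder cancer", "breast cancer",
    "colon cancer", "gastric cancer", "kidney cancer", "leukemia",
    "liver cancer", "lung cancer", "ovary cancer", "prostate cancer",
    "skin cancer", "thyroid cancer", "tongue cancer",
)

#: Classes removed when deriving the 10-class setting from the 15-class one.
CANCER_TYPES_EXCLUDED_10 = (
    "bile duct cancer", "gastric cancer", "liver cancer",
    "ovary cancer", "thyroid cancer",
)

#: The retained 10-class vocabulary.
CANCER_TYPES_10 = tuple(c for c in CANCER_TYPES_15
                        if c not in CANCER_TYPES_EXCLUDED_10)


@dataclass
class PeptideRecord:
    """One peptide: identifier, sanitized sequence, non-empty label set."""

    pid: str
    sequence: str
    labels: frozenset[str]

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"peptide {self.pid!r}: empty sequence")
        if not self.labels:
            raise ValueError(f"peptide {self.pid!r}: empty label set")
        self.labels = frozenset(self.labels)


@dataclass
class TranscriptMap:
    """Peptide→transcript membership plus per-transcript incidence counts."""

    membership: dict[str, list[str]]
    frequency: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.frequency:
            freq: dict[str, int] = {}
            for rids in self.membership.values():
                for rid in rids:
                    freq[rid] = freq.get(rid, 0) + 1
            self.frequency = freq

    @property
    def n_transcripts(self) -> int:
        return len(self.frequency)


class LabelVocabulary:
    """Ordered (lexicographic) cancer-type name → column index mapping."""

    def __init__(self, names):
        self.names: list[str] = sorted(set(names))
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelVocabulary) and self.names == other.names

    @classmethod
    def from_records(cls, records) -> "LabelVocabulary":
        names: set[str] = set()
        for r in records:
            names |= r.labels
        return cls(names)


@dataclass
class SplitIndices:
    """Disjoint train/val/test index lists covering 0..N-1."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "train": self.train.tolist(), "val": self.val.tolist(),
            "test": self.test.tolist(), "seed": self.seed,
            "fractions": list(self.fractions),
        }))

    @classmethod
    def from_json(cls, path) -> "SplitIndices":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["train"], dtype=int), np.asarray(d["val"], dtype=int),
                   np.asarray(d["test"], dtype=int), int(d["seed"]),
                   tuple(d["fractions"]))


def sanitize_sequence(seq: str, pid: str = "?") -> str:
    """Upper-case and map residues outside the 21-letter alphabet to 'X'."""
    seq = seq.strip().upper()
    if any(c not in ALPHABET for c in seq):
        bad = sorted({c for c in seq if c not in ALPHABET})
        logger.warning("peptide %s: nonstandard residues %s replaced by 'X'",
                       pid, "".join(bad))
        seq = "".join(c if c in ALPHABET else "X" for c in seq)
    return seq


def _read_tsv_rows(path) -> tuple[list[str], list[list[str]]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    rows = [ln.split("\t") for ln in lines[1:] if ln.strip()]
    return header, rows


def parse_peptides(peptide_table_path, fasta_path=None) -> list[PeptideRecord]:
    """Read a peptide table (TSV), optionally taking sequences from a FASTA.

    The TSV must have a ``pid<TAB>sequence<TAB>labels`` header; when a FASTA is
    given its records (keyed on pid) override/supply the sequence column.
    """
    header, rows = _read_tsv_rows(peptide_table_path)
    cols = {name: i for i, name in enumerate(header)}
    if "pid" not in cols or "labels" not in cols:
        raise ValueError(f"{peptide_table_path}: expected columns pid, sequence, labels")
    fasta_seqs: dict[str, str] = {}
    if fasta_path is not None:
        fasta_seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for row in rows:
        pid = row[cols["pid"]].strip()
        if pid in seen:
            raise ValueError(f"duplicate pid {pid!r} in {peptide_table_path}")
        seen.add(pid)
        seq = fasta_seqs.get(pid)
        if seq is None and "sequence" in cols:
            seq = row[cols["sequence"]].strip()
        if not seq:
            raise ValueError(f"peptide {pid!r}: missing sequence")
        label_field = row[cols["labels"]].strip()
        labels = {t.strip() for t in label_field.split(LABEL_DELIM) if t.strip()}
        if not labels:
            raise ValueError(f"peptide {pid!r}: empty label field")
        records.append(PeptideRecord(pid, sanitize_sequence(seq, pid), frozenset(labels)))
    return records


def parse_transcript_map(map_table_path, records=None) -> TranscriptMap:
    """Read a peptide→transcript map (TSV ``pid<TAB>rids``).

    Transcript frequency counts each (pid, rid) incidence once, matching how
    often each transcript appears across the file.  If ``records`` is given,
    pids absent from it are an error.
    """
    header, rows = _read_tsv_rows(map_table_path)
    cols = {name: i for i, name in enumerate(header)}
    if "pid" not in cols or "rids" not in cols:
        raise ValueError(f"{map_table_path}: expected columns pid, rids")
    known = {r.pid for r in records} if records is not None else None

    membership: dict[str, list[str]] = {}
    for row in rows:
        pid = row[cols["pid"]].strip()
        if known is not None and pid not in known:
            raise ValueError(f"transcript map pid {pid!r} absent from the peptide table")
        rid_field = row[cols["rids"]].strip() if len(row) > cols["rids"] else ""
        rids = [t.strip() for t in rid_field.split(LABEL_DELIM) if t.strip()]
        if not rids:
            raise ValueError(f"peptide {pid!r}: empty transcript list")
        membership[pid] = rids
    return TranscriptMap(membership)


def write_peptides(records, table_path, fasta_path=None) -> None:
    """Write records back to the TSV (and optionally FASTA) dialect."""
    lines = ["pid\tsequence\tlabels"]
    for r in records:
        lines.append(f"{r.pid}\t{r.sequence}\t{LABEL_DELIM.join(sorted(r.labels))}")
    Path(table_path).write_text("\n".join(lines) + "\n")
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for r in records:
                fh.write(f">{r.pid}\n{r.sequence}\n")


def write_transcript_map(tmap: TranscriptMap, path) -> None:
    lines = ["pid\trids"]
    for pid, rids in tmap.membership.items():
        lines.append(f"{pid}\t{LABEL_DELIM.join(rids)}")
    Path(path).write_text("\n".join(lines) + "\n")


def filter_classes(records, keep_names) -> tuple[list[PeptideRecord], int]:
    """Restrict labels to ``keep_names``; drop records left label-less.

    This is how the 10-class benchmark derives from the 15-class one: the five
    smallest classes are removed and peptides annotated only with those
    classes are dropped.  Returns (retained records, number dropped).
    """
    keep = set(keep_names)
    if not keep:
        raise ValueError("keep_names must be non-empty")
    kept: list[PeptideRecord] = []
    dropped = 0
    for r in records:
        labels = r.labels & keep
        if labels:
            kept.append(PeptideRecord(r.pid, r.sequence, frozenset(labels)))
        else:
            dropped += 1
    return kept, dropped


def encode_labels(records, vocab: LabelVocabulary) -> np.ndarray:
    """Binary N×C label matrix; row i ↔ records[i], column j ↔ vocab.names[j]."""
    Y = np.zeros((len(records), len(vocab)), dtype=np.int8)
    for i, r in enumerate(records):
        for name in r.labels:
            if name not in vocab:
                raise ValueError(f"label {name!r} not in vocabulary")
            Y[i, vocab.index[name]] = 1
    return Y


def split_dataset(n: int, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitIndices:
    """Uniform random 80/10/10 split; val and test sizes floor, remainder to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    if n < 3 or n_val < 1 or n_test < 1:
        raise ValueError(f"n={n} too small for non-empty train/val/test splits")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(train=np.sort(perm[n_val + n_test:]),
                        val=np.sort(perm[:n_val]),
                        test=np.sort(perm[n_val:n_val + n_test]),
                        seed=seed, fractions=tuple(fractions))
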