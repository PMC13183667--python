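"""Synthetic peptide/transcript benchmark generator with a planted signal.

The generator emits exactly the TSV/FASTA dialects the parsers read, at the
scale of the curated ncPEP benchmark (about four thousand peptides, three
thousand transcripts, 10–15 imbalanced cancer-type classes), together with
the ground truth used to plant the signal.  Three signal modes make the
pipeline's claims testable in isolation:

* ``hyperedge`` — each transcript carries a sparse cancer-type profile and a
  peptide's labels are the union of its transcripts' profiles (optionally
  corrupted by cell-flip noise).  Sequences are uniform random residues, so
  only the hypergraph structure is informative.
* ``sequence`` — labels are drawn per peptide and each class plants a short
  motif into its positive peptides with a configurable insertion probability;
  transcript membership is random and label-independent, so only the
  sequence is informative.
* ``mixed`` — hyperedge-driven labels plus motif planting for those labels.

Class imbalance follows a geometric profile (ratio ≈ 10:1 between the
largest and smallest of 15 classes, matching the benchmark's spread) unless
explicit class weights are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import AMINO_ACIDS, PeptideRecord, TranscriptMap, write_peptides, \
    write_transcript_map

_CLASS_DECAY = 0.85  # geometric imbalance profile across classes


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the benchmark's published scale."""

    n_peptides: int = 4019
    n_rnas: int = 3066
    n_classes: int = 15
    peptides_per_rna_mean: float = 2.0
    peptides_per_rna_dispersion: float = 1.0  # negative-binomial size; small = overdispersed
    labels_per_transcript: int = 2
    signal_mode: str = "hyperedge"  # hyperedge | sequence | mixed
    noise_rate: float = 0.0
    motif_len: int = 5
    motif_strength: float = 0.9
    extra_label_rate: float = 0.3  # sequence mode: Poisson rate of extra labels
    seq_len_range: tuple[int, int] = (10, 50)
    class_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.n_peptides, self.n_rnas, self.n_classes - 1) <= 0:
            raise ValueError("counts must be positive and n_classes >= 2")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if self.labels_per_transcript > self.n_classes:
            raise ValueError("labels_per_transcript cannot exceed n_classes")
        if self.signal_mode not in ("hyperedge", "sequence", "mixed"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        if self.class_weights is None:
            w = _CLASS_DECAY ** np.arange(self.n_classes)
            self.class_weights = w / w.sum()
        else:
            w = np.asarray(self.class_weights, dtype=float)
            self.class_weights = w / w.sum()


@dataclass
class SimTruth:
    """Ground truth behind one generated dataset."""

    class_names: list[str]
    transcript_profiles: dict[str, list[str]]
    noiseless_labels: dict[str, list[str]]
    motifs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "class_names": self.class_names,
            "transcript_profiles": self.transcript_profiles,
            "noiseless_labels": self.noiseless_labels,
            "motifs": self.motifs,
        }))


@dataclass
class SimDataset:
    records: list[PeptideRecord]
    tmap: TranscriptMap
    truth: SimTruth
    config: SimConfig


def _class_names(c: int) -> list[str]:
    return [f"class_{k:02d}" for k in range(c)]


def _draw_membership(cfg: SimConfig, rng: np.random.Generator) -> dict[str, list[int]]:
    """Transcript → member-peptide sets with negative-binomial sizes.

    Every peptide is guaranteed at least one transcript (extra slots are added
    to random transcripts when the drawn sizes cannot cover all peptides), so
    hyperedge-driven labels are defined for every vertex.
    """
    m = cfg.n_rnas
    r = cfg.peptides_per_rna_dispersion
    mean_extra = max(cfg.peptides_per_rna_mean - 1.0, 0.0)
    lam = rng.gamma(shape=r, scale=mean_extra / r, size=m) if mean_extra > 0 else np.zeros(m)
    sizes = 1 + rng.poisson(lam)
    while sizes.sum() < cfg.n_peptides:
        sizes[rng.integers(m)] += 1
    slots = np.repeat(np.arange(m), sizes)
    rng.shuffle(slots)
    members: dict[int, set[int]] = {e: set() for e in range(m)}
    order = rng.permutation(cfg.n_peptides)
    for i, pep in enumerate(order):  # first pass covers every peptide once
        members[slots[i]].add(int(pep))
    for s in slots[cfg.n_peptides:]:
        members[int(s)].add(int(rng.integers(cfg.n_peptides)))
    return {f"r{e:04d}": sorted(mem) for e, mem in members.items() if mem}


def _random_sequence(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=length))


def _distinct_motifs(cfg: SimConfig, rng: np.random.Generator,
                     names: list[str]) -> dict[str, str]:
    motifs: dict[str, str] = {}
    used: set[str] = set()
    for name in names:
        while True:
            motif = "".join(AMINO_ACIDS[i] for i in
                            rng.integers(len(AMINO_ACIDS), size=cfg.motif_len))
            if motif not in used:
                used.add(motif)
                motifs[name] = motif
                break
    return motifs


def _apply_flip_noise(label_sets: list[set[str]], names: list[str],
                      rate: float, rng: np.random.Generator) -> list[set[str]]:
    """Flip each (peptide, class) cell independently; keep every row non-empty."""
    if rate <= 0:
        return [set(s) for s in label_sets]
    noisy = []
    for orig in label_sets:
        flipped = {n for n in names
                   if (n in orig) != (rng.random() < rate)}
        if not flipped:  # restore one of the original labels, chosen uniformly
            flipped = {sorted(orig)[rng.integers(len(orig))]}
        noisy.append(flipped)
    return noisy


def simulate(cfg: SimConfig) -> SimDataset:
    """Generate an in-memory dataset (records, transcript map, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    names = _class_names(cfg.n_classes)

    membership_by_rna = _draw_membership(cfg, rng)
    pids = [f"p{i:05d}" for i in range(cfg.n_peptides)]
    # invert to peptide → transcript lists (transcripts in id order)
    pep_rnas: dict[str, list[str]] = {pid: [] for pid in pids}
    for rid in sorted(membership_by_rna):
        for v in membership_by_rna[rid]:
            pep_rnas[pids[v]].append(rid)

    profiles: dict[str, list[str]] = {}
    if cfg.signal_mode in ("hyperedge", "mixed"):
        for rid in sorted(membership_by_rna):
            chosen = rng.choice(cfg.n_classes, size=cfg.labels_per_transcript,
                                replace=False, p=cfg.class_weights)
            profiles[rid] = sorted(names[k] for k in chosen)
        clean = [set().union(*(profiles[rid] for rid in pep_rnas[pid]))
                 for pid in pids]
    else:  # sequence mode: labels drawn per peptide, membership uninformative
        clean = []
        for _ in pids:
            extra = min(int(rng.poisson(cfg.extra_label_rate)), cfg.n_classes - 1)
            chosen = rng.choice(cfg.n_classes, size=1 + extra, replace=False,
                                p=cfg.class_weights)
            clean.append({names[k] for k in chosen})

    motifs: dict[str, str] = {}
    if cfg.signal_mode in ("sequence", "mixed"):
        motifs = _distinct_motifs(cfg, rng, names)

    lo, hi = cfg.seq_len_range
    sequences = []
    for labels in clean:
        seq = _random_sequence(rng, lo, hi)
        for name in sorted(labels):
            if motifs and len(seq) >= cfg.motif_len and rng.random() < cfg.motif_strength:
                motif = motifs[name]
                pos = int(rng.integers(0, len(seq) - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
        sequences.append(seq)

    noisy = _apply_flip_noise(clean, names, cfg.noise_rate, rng)
    records = [PeptideRecord(pid, seq, frozenset(labels))
               for pid, seq, labels in zip(pids, sequences, noisy)]
    tmap = TranscriptMap({pid: pep_rnas[pid] for pid in pids})
    truth = SimTruth(class_names=names,
                     transcript_profiles=profiles,
                     noiseless_labels={pid: sorted(s) for pid, s in zip(pids, clean)},
                     motifs=motifs)
    return SimDataset(records=records, tmap=tmap, truth=truth, config=cfg)


def generate(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Generate a dataset and write peptides.tsv/.fasta, transcript_map.tsv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate(cfg)
    paths = {
        "peptides_tsv": out / "peptides.tsv",
        "peptides_fasta": out / "peptides.fasta",
        "transcript_map": out / "transcript_map.tsv",
        "truth": out / "truth.json",
    }
    write_peptides(ds.records, paths["peptides_tsv"], paths["peptides_fasta"])
    write_transcript_map(ds.tmap, paths["transcript_map"])
    ds.truth.to_json(paths["truth"])
    return paths


def summarize(records, tmap: TranscriptMap) -> dict:
    """Class sizes, label-cardinality histogram, peptides-per-transcript histogram."""
    class_counts: dict[str, int] = {}
    card_hist: dict[int, int] = {}
    for r in records:
        card_hist[len(r.labels)] = card_hist.get(len(r.labels), 0) + 1
        for name in r.labels:
            class_counts[name] = class_counts.get(name, 0) + 1
    per_rna: dict[str, int] = {}
    for rids in tmap.membership.values():
        for rid in set(rids):
            per_rna[rid] = per_rna.get(rid, 0) + 1
    size_hist: dict[int, int] = {}
    for s in per_rna.values():
        size_hist[s] = size_hist.get(s, 0) + 1
    return {
        "n_peptides": len(records),
        "n_transcripts": len(per_rna),
        "class_counts": dict(sorted(class_counts.items())),
        "label_cardinality_hist": dict(sorted(card_hist.items())),
        "peptides_per_transcript_hist": dict(sorted(size_hist.items())),
        "mean_label_cardinality": float(np.mean([len(r.labels) for r in records])),
    }
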