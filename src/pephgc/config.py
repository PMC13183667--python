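"""Structured run configuration (YAML, versioned with ``schema_version``).

One file drives every CLI stage::

    schema_version: 1
    data:
      peptide_table: peptides.tsv
      fasta: peptides.fasta          # optional
      transcript_map: transcript_map.tsv
      keep_classes: null             # optional list for class filtering
    simulate: { n_peptides: 2000, n_rnas: 600, ... }   # SimConfig fields
    model:
      encoder: textcnn
      encoder_config: { embed_dim: 64, kernel_widths: [3, 4, 5], ... }
      conv: hgnnp
      conv_depth: 2
      head_hidden: [64]
      fusion: concat
      loss: ce
      loss_params: {}
      dropout: 0.1
      edge_weights: uniform          # uniform | frequency
    train: { epochs: 200, lr: 0.001, patience: 30, ... }

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .encoder import EncoderConfig
from .model import ModelSpec
from .simulate import SimConfig
from .training import TrainConfig

SCHEMA_VERSION = 1


def _build(cls, d: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r} section: {sorted(unknown)}")
    kwargs = dict(d)
    for key in ("kernel_widths", "head_hidden", "seq_len_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


class RunConfig:
    """Parsed, validated configuration for one pipeline run."""

    def __init__(self, raw: dict):
        version = raw.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {version!r} "
                             f"(expected {SCHEMA_VERSION})")
        self.data: dict = raw.get("data", {})
        self.sim_config: SimConfig | None = None
        if "simulate" in raw:
            self.sim_config = _build(SimConfig, raw["simulate"], "simulate")
        model_raw = dict(raw.get("model", {}))
        self.edge_weights: str = model_raw.pop("edge_weights", "uniform")
        if "encoder_config" in model_raw:
            model_raw["encoder_config"] = _build(EncoderConfig,
                                                 model_raw["encoder_config"],
                                                 "model.encoder_config")
        if "head_hidden" in model_raw:
            model_raw["head_hidden"] = tuple(model_raw["head_hidden"])
        self.model_spec = _build(ModelSpec, model_raw, "model")
        self.train_config = _build(TrainConfig, raw.get("train", {}), "train")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))
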