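"""Attention extraction and diffing, and HDF5 checkpointing.

Every global-attention head produces a weight vector over the L encoded
positions that sums to 1, so the whole model's attention for one protein is
a (n_blocks * n_heads) x L map — and the difference between two such maps
(e.g. before vs after fine-tuning) has rows summing to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .model import ModelConfig, ProteinModel, build_model

__all__ = ["AttentionMap", "extract_attention", "attention_diff",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class AttentionMap:
    """Rows are (block, head) pairs in block-major order; columns are positions."""

    values: np.ndarray          # (n_blocks * n_heads, L)
    head_labels: tuple          # ((block, head), ...)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def row_label(self, i: int) -> str:
        b, h = self.head_labels[i]
        return f"{b}.{h}"

    def total_attention(self) -> np.ndarray:
        """Column sums across heads (the 'total attention per residue' bar)."""
        return self.values.sum(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            L = self.values.shape[1]
            fh.write("head\t" + "\t".join(f"pos{i}" for i in range(L)) + "\n")
            for i, row in enumerate(self.values):
                fh.write(self.row_label(i) + "\t" +
                         "\t".join(f"{v:.6g}" for v in row) + "\n")


def extract_attention(model: ProteinModel, token_ids: np.ndarray,
                      annotations: np.ndarray | None = None) -> AttentionMap:
    """Attention weights of every head for a single encoded sequence.

    ``token_ids`` is one sequence of length L; the annotation input defaults
    to the all-zero vector (the fine-tuning/inference convention).
    """
    token_ids = np.asarray(token_ids)
    if token_ids.ndim != 1:
        raise ValueError("extract_attention takes a single un-batched sequence")
    if annotations is None:
        annotations = np.zeros(model.config.n_annotations)
    collected: list = []
    model.forward(token_ids[None, :], np.asarray(annotations)[None, :],
                  collect_attention=collected)
    values = np.concatenate([z for z in collected], axis=0)   # rows appended per head
    labels = tuple((b, h) for b in range(model.config.n_blocks)
                   for h in range(model.config.n_heads))
    return AttentionMap(values=values, head_labels=labels)


def attention_diff(map_a: AttentionMap, map_b: AttentionMap) -> AttentionMap:
    """Elementwise map_b - map_a; every row sums to ~0."""
    if map_a.values.shape != map_b.values.shape or map_a.head_labels != map_b.head_labels:
        raise ValueError("attention maps have mismatched shapes or head labels")
    return AttentionMap(values=map_b.values - map_a.values,
                        head_labels=map_a.head_labels)


# ------------------------------------------------------------- checkpointing

def save_checkpoint(model: ProteinModel, path) -> None:
    """Single-file HDF5 container: config as a JSON attribute + named weights."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(model.config.to_dict())
        grp = f.create_group("weights")
        for name, p in model.named_parameters().items():
            grp.create_dataset(name, data=p.data)


def load_checkpoint(path, expect_config: ModelConfig | None = None) -> ProteinModel:
    """Rebuild a model bit-exactly from a checkpoint.

    Fails loudly if the stored config disagrees with ``expect_config`` or if
    any weight tensor is missing or mis-shaped.
    """
    with h5py.File(path, "r") as f:
        try:
            config = ModelConfig.from_dict(json.loads(f.attrs["config"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"corrupt or incompatible checkpoint {path}: {exc}") from exc
        if expect_config is not None and config != expect_config:
            raise ValueError(
                f"checkpoint config {config} does not match expected {expect_config}")
        model = build_model(config, rng=0)
        weights = f["weights"]
        for name, p in model.named_parameters().items():
            if name not in weights:
                raise ValueError(f"checkpoint missing weight tensor {name!r}")
            data = np.asarray(weights[name])
            if data.shape != p.data.shape:
                raise ValueError(f"weight {name!r} has shape {data.shape}, "
                                 f"expected {p.data.shape}")
            p.data = data.astype(np.float64)
    return model
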