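"""Readers and writers for the package's plain-text formats.

- FASTA for sequences (via Biopython; multi-record, wrapped lines).
- Annotation tables: TSV with columns ``protein_id`` and ``annotation_ids``
  (comma-separated; empty field = no annotations).
- Global label tables: TSV ``id`` / ``label``.
- Local label tables: TSV ``id`` / per-residue label string of the same
  length as the sequence.
- YAML model configs.

Malformed records raise with the offending line number rather than being
skipped silently.
"""

from __future__ import annotations

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ModelConfig

__all__ = ["read_fasta", "write_fasta", "read_annotation_table",
           "write_annotation_table", "read_global_labels", "read_local_labels",
           "load_model_config", "save_model_config"]


def read_fasta(path) -> list:
    """[(id, sequence), ...] — rejects records with empty sequences."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    return out


def write_fasta(records, path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records),
                str(path), "fasta")


def read_annotation_table(path) -> dict:
    """{protein_id: frozenset of annotation ids} from a two-column TSV."""
    out: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_id", "annotation_ids"]:
            raise ValueError(f"{path}:1: expected header 'protein_id\\tannotation_ids', "
                             f"got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields, "
                                 f"got {len(parts)}")
            pid, field = parts
            if pid in out:
                raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            out[pid] = frozenset(a for a in field.split(",") if a)
    return out


def write_annotation_table(annotations: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tannotation_ids\n")
        for pid, annots in annotations.items():
            fh.write(f"{pid}\t{','.join(sorted(annots))}\n")


def read_global_labels(path, label_type: str) -> dict:
    """{id: label} from an ``id``/``label`` TSV; numeric parse by label type."""
    cast = float if label_type == "continuous" else int
    out: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "label"]:
            raise ValueError(f"{path}:1: expected header 'id\\tlabel', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            try:
                out[parts[0]] = cast(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad label {parts[1]!r}") from exc
    return out


def read_local_labels(path, sequences: dict) -> dict:
    """{id: per-residue int array}; label strings must match sequence lengths."""
    out: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "labels"]:
            raise ValueError(f"{path}:1: expected header 'id\\tlabels', got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            pid, labstr = parts
            if pid in sequences and len(labstr) != len(sequences[pid]):
                raise ValueError(f"{path}:{lineno}: label string length {len(labstr)} "
                                 f"!= sequence length {len(sequences[pid])} for {pid!r}")
            try:
                out[pid] = np.array([int(c) for c in labstr], dtype=np.int64)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer label character") from exc
    return out


def load_model_config(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: model config must be a YAML mapping")
    try:
        return ModelConfig.from_dict(data)
    except TypeError as exc:
        raise ValueError(f"{path}: unknown or missing config field: {exc}") from exc


def save_model_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
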