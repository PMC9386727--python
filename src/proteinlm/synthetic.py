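"""Synthetic protein-like corpora and toy tasks with planted, recoverable signal.

Sequences are i.i.d. draws over the 20 standard residues (uniform by
default); short motifs are written over the background at random offsets and
each planted motif attaches its annotation id.  Toy tasks reuse the same
motifs so that pretraining on a generated corpus yields features that
transfer to the tasks:

- ``local_binary``: an N-terminal hydrophobic motif mimicking a signal
  peptide; residues inside the motif are labeled 1.
- ``global_categorical``: each sequence carries exactly one of k class
  motifs; the label is which one.
- ``global_continuous``: the label is a noisy linear function of the number
  of planted copies of one motif.

The planted signal is exact string evidence, so a simple motif-matching
oracle (`motif_oracle_accuracy`) can verify that each task is solvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vocab import STANDARD_RESIDUES

__all__ = ["MotifRule", "CorpusSpec", "generate_corpus", "TaskSpec",
           "generate_toy_task", "motif_oracle_accuracy",
           "SIGNAL_MOTIF", "CLASS_MOTIFS", "COUNT_MOTIF"]

# Shared motif set: the corpus generator plants these, and the toy tasks label
# them, so pretrained features are relevant to every task.
SIGNAL_MOTIF = "LLALLLWA"          # hydrophobic N-terminal stretch
CLASS_MOTIFS = ("WCYHCW", "KRKHKR", "NDTGSD", "FMFIMF", "PGPYGP", "EQEQED", "VTVAVT")
COUNT_MOTIF = "WHWHWH"


@dataclass(frozen=True)
class MotifRule:
    motif: str
    annotation_id: str
    p_insert: float

    def __post_init__(self):
        if any(c not in STANDARD_RESIDUES for c in self.motif):
            raise ValueError(f"motif {self.motif!r} uses non-standard residues")
        if not 0.0 <= self.p_insert <= 1.0:
            raise ValueError("p_insert must lie in [0, 1]")


def default_motif_rules(p_insert: float = 0.35) -> tuple:
    """One rule per shared motif (the three class motifs most tasks use,
    plus the signal and copy-count motifs)."""
    motifs = (SIGNAL_MOTIF,) + CLASS_MOTIFS[:3] + (COUNT_MOTIF,)
    return tuple(MotifRule(m, f"MOTIF:{m}", p_insert) for m in motifs)


@dataclass(frozen=True)
class CorpusSpec:
    n_records: int = 5000
    min_length: int = 40
    max_length: int = 80
    background: tuple = tuple(1.0 / 20 for _ in STANDARD_RESIDUES)
    motif_rules: tuple = field(default_factory=default_motif_rules)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.background) - 1.0) > 1e-9 or any(p < 0 for p in self.background):
            raise ValueError("background must be a probability vector over 20 residues")
        longest = max((len(r.motif) for r in self.motif_rules), default=0)
        if longest > self.min_length:
            raise ValueError("motif longer than the minimum sequence length")

    @property
    def annotation_ids(self) -> tuple:
        return tuple(r.annotation_id for r in self.motif_rules)


def _background_sequence(rng: np.random.Generator, length: int, background) -> list:
    letters = rng.choice(list(STANDARD_RESIDUES), size=length, p=list(background))
    return list(letters)


def _plant(seq: list, motif: str, offset: int) -> None:
    seq[offset:offset + len(motif)] = list(motif)


def generate_corpus(spec: CorpusSpec) -> list:
    """Materialize (id, sequence, annotation-id frozenset) records.

    Motif j is written at a uniform offset with probability ``p_insert`` and
    its annotation id attached iff it was planted.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_records):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = _background_sequence(rng, length, spec.background)
        annots = set()
        for rule in spec.motif_rules:
            if rng.random() < rule.p_insert:
                offset = int(rng.integers(0, length - len(rule.motif) + 1))
                _plant(seq, rule.motif, offset)
                annots.add(rule.annotation_id)
        records.append((f"SYN{i:06d}", "".join(seq), frozenset(annots)))
    return records


@dataclass(frozen=True)
class TaskSpec:
    """A fine-tuning dataset with declared resolution and label type.

    ``records`` entries are (id, sequence, label); local labels are
    per-residue integer arrays of the same length as the sequence, global
    labels are an int (binary/categorical) or float (continuous).
    """

    resolution: str            # "local" | "global"
    label_type: str            # "binary" | "categorical" | "continuous"
    n_classes: int | None
    train: tuple
    valid: tuple
    test: tuple

    def __post_init__(self):
        if self.resolution not in ("local", "global"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        if self.label_type not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown label type {self.label_type!r}")
        ids = [r[0] for split in (self.train, self.valid, self.test) for r in split]
        if len(set(ids)) != len(ids):
            raise ValueError("splits must be disjoint by sequence id")


def _split(records: list, rng: np.random.Generator) -> tuple:
    """70/15/15 split, disjoint by record."""
    idx = rng.permutation(len(records))
    n_train = int(round(0.70 * len(records)))
    n_valid = int(round(0.15 * len(records)))
    train = tuple(records[i] for i in idx[:n_train])
    valid = tuple(records[i] for i in idx[n_train:n_train + n_valid])
    test = tuple(records[i] for i in idx[n_train + n_valid:])
    return train, valid, test


def generate_toy_task(kind: str, n: int, seed: int, *,
                      min_length: int = 40, max_length: int = 60,
                      n_classes: int = 3) -> TaskSpec:
    """Build a planted-signal task of ``n`` sequences with a 70/15/15 split."""
    if n < 30:
        raise ValueError("n must be at least 30")
    rng = np.random.default_rng(seed)
    background = tuple(1.0 / 20 for _ in STANDARD_RESIDUES)
    records = []
    if kind == "local_binary":
        m = len(SIGNAL_MOTIF)
        for i in range(n):
            length = int(rng.integers(min_length, max_length + 1))
            seq = _background_sequence(rng, length, background)
            offset = int(rng.integers(0, 6))     # signal-peptide-like N-terminal placement
            _plant(seq, SIGNAL_MOTIF, offset)
            labels = np.zeros(length, dtype=np.int64)
            labels[offset:offset + m] = 1
            records.append((f"LOC{i:06d}", "".join(seq), labels))
        res, lt, k = "local", "binary", None
    elif kind == "global_categorical":
        if n_classes > len(CLASS_MOTIFS):
            raise ValueError(f"at most {len(CLASS_MOTIFS)} classes supported")
        for i in range(n):
            cls = i % n_classes                  # stratified: balanced within +/-1
            length = int(rng.integers(min_length, max_length + 1))
            seq = _background_sequence(rng, length, background)
            motif = CLASS_MOTIFS[cls]
            offset = int(rng.integers(0, length - len(motif) + 1))
            _plant(seq, motif, offset)
            records.append((f"CAT{i:06d}", "".join(seq), cls))
        res, lt, k = "global", "categorical", n_classes
    elif kind == "global_continuous":
        m = len(COUNT_MOTIF)
        for i in range(n):
            length = int(rng.integers(min_length, max_length + 1))
            seq = _background_sequence(rng, length, background)
            copies = int(rng.integers(0, 4))
            slots = rng.permutation(length // m)[:copies]   # non-overlapping slots
            for slot in slots:
                _plant(seq, COUNT_MOTIF, slot * m)
            label = float(copies) + rng.normal(0.0, 0.1)
            records.append((f"CON{i:06d}", "".join(seq), label))
        res, lt, k = "global", "continuous", None
    else:
        raise ValueError(f"unknown task kind {kind!r}")
    train, valid, test = _split(records, rng)
    return TaskSpec(resolution=res, label_type=lt, n_classes=k,
                    train=train, valid=valid, test=test)


def motif_oracle_accuracy(task: TaskSpec) -> float:
    """Accuracy of literal motif matching on the test split.

    Validates that the planted signal is recoverable (it upper-bounds what a
    sequence model can learn).  For continuous tasks the 'accuracy' is the
    fraction of test labels within 3 noise standard deviations of the
    motif-count prediction.
    """
    correct = 0
    for _, seq, label in task.test:
        if task.label_type == "binary" and task.resolution == "local":
            off = seq.find(SIGNAL_MOTIF)
            pred = np.zeros(len(seq), dtype=np.int64)
            if off >= 0:
                pred[off:off + len(SIGNAL_MOTIF)] = 1
            correct += int(np.array_equal(pred, label))
        elif task.label_type == "categorical":
            hits = [c for c, m in enumerate(CLASS_MOTIFS[:task.n_classes]) if m in seq]
            correct += int(len(hits) == 1 and hits[0] == label)
        else:
            pred = float(seq.count(COUNT_MOTIF))
            correct += int(abs(pred - label) <= 0.3)
    return correct / len(task.test)
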