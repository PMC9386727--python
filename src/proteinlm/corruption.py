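"""Corruption scheme for denoising pretraining.

Inputs are damaged, targets stay clean: each token is independently replaced
with a uniformly drawn token (the draw may return the original), each present
annotation is dropped with a fixed probability, each absent annotation is
spuriously switched on with a small probability, and for a fraction of
proteins the whole annotation input is blanked to force annotation prediction
from sequence alone.  Special-token positions (START/END/PAD) are eligible
for replacement by default; set ``corrupt_specials=False`` to exempt them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vocab import (AnnotationVocabulary, EncodedSequence, TokenVocabulary,
                    build_token_vocabulary, encode_annotations, encode_sequence)

__all__ = ["CorruptionConfig", "PretrainingExample", "corrupt_tokens",
           "corrupt_annotations", "make_pretraining_example", "example_stream"]


@dataclass(frozen=True)
class CorruptionConfig:
    p_token_replace: float = 0.05
    p_annot_remove: float = 0.25
    p_annot_add: float = 0.0001
    p_annot_blank: float = 0.5
    corrupt_specials: bool = True

    def __post_init__(self):
        for name in ("p_token_replace", "p_annot_remove", "p_annot_add", "p_annot_blank"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class PretrainingExample:
    """Corrupted inputs paired with the clean targets for the same window."""

    input_tokens: np.ndarray
    input_annotations: np.ndarray
    target_tokens: np.ndarray
    target_annotations: np.ndarray

    def __post_init__(self):
        if len(self.input_tokens) != len(self.target_tokens):
            raise ValueError("input and target token sequences must have equal length")


def corrupt_tokens(tokens: np.ndarray, cfg: CorruptionConfig, rng: np.random.Generator,
                   vocab: TokenVocabulary | None = None) -> np.ndarray:
    """Independently replace each position with a uniform random token."""
    vocab = vocab or build_token_vocabulary()
    tokens = np.asarray(tokens)
    hit = rng.random(tokens.shape) < cfg.p_token_replace
    replacement = rng.integers(0, len(vocab), size=tokens.shape)
    if not cfg.corrupt_specials:
        specials = np.isin(tokens, [vocab.start_id, vocab.end_id, vocab.pad_id])
        hit &= ~specials
    return np.where(hit, replacement, tokens)


def corrupt_annotations(bits: np.ndarray, cfg: CorruptionConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Blank wholesale, or drop present bits / add absent bits independently.

    Blanking is decided per protein before any per-bit sampling; a blanked
    vector consumes only the single blanking draw.
    """
    bits = np.asarray(bits)
    if rng.random() < cfg.p_annot_blank:
        return np.zeros_like(bits)
    u = rng.random(bits.shape)
    present = bits == 1
    keep = present & (u >= cfg.p_annot_remove)
    add = ~present & (u < cfg.p_annot_add)
    return (keep | add).astype(bits.dtype)


def make_pretraining_example(record, cfg: CorruptionConfig, target_len: int,
                             rng: np.random.Generator,
                             token_vocab: TokenVocabulary | None = None,
                             annot_vocab: AnnotationVocabulary | None = None,
                             ) -> PretrainingExample:
    """Encode one (sequence, annotation set) record and corrupt the input copy.

    Input and target share the same sampled window; targets are never blanked
    or otherwise corrupted.
    """
    sequence, annotation_ids = record
    if annot_vocab is None:
        raise ValueError("an AnnotationVocabulary is required")
    token_vocab = token_vocab or build_token_vocabulary()
    encoded: EncodedSequence = encode_sequence(sequence, target_len, rng, token_vocab)
    clean_bits = encode_annotations(annotation_ids, annot_vocab)
    return PretrainingExample(
        input_tokens=corrupt_tokens(encoded.token_ids, cfg, rng, token_vocab),
        input_annotations=corrupt_annotations(clean_bits, cfg, rng),
        target_tokens=encoded.token_ids.copy(),
        target_annotations=clean_bits,
    )


def example_stream(records, cfg: CorruptionConfig, rng: np.random.Generator,
                   annot_vocab: AnnotationVocabulary,
                   target_len_fn, batch_size: int):
    """Endless batches of pretraining examples cycling over ``records``.

    ``records`` is a sequence of (id, sequence, annotation set) triples;
    ``target_len_fn(step)`` supplies the encoding length for each step, so a
    length scheduler can be injected.
    """
    token_vocab = build_token_vocabulary()
    n = len(records)
    if n == 0:
        raise ValueError("empty corpus")
    step = 0
    cursor = 0
    while True:
        target_len = target_len_fn(step)
        batch = []
        for _ in range(batch_size):
            _, seq, annots = records[cursor]
            cursor = (cursor + 1) % n
            batch.append(make_pretraining_example(
                (seq, annots), cfg, target_len, rng, token_vocab, annot_vocab))
        yield step, target_len, batch
        step += 1
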