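"""Dual-task denoising objective and the pretraining loop.

The per-example loss is the literal summed form

    L = - sum_{i=1..l} log p(token_i = true token)
        - sum_{j} [ A_j log Ahat_j + (1 - A_j) log(1 - Ahat_j) ]

i.e. categorical cross-entropy over every sequence position (PAD included by
default; an optional mask excludes it) plus binary cross-entropy over the
annotation vector.  The batch loss is the mean over examples.  Probabilities
are clipped to [eps, 1-eps] with eps = 1e-7 before the logarithms.

Encoding length is switched on a step schedule rather than wall-clock, so
runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .corruption import CorruptionConfig, example_stream
from .layers import Adam
from .model import ModelOutputs, ProteinModel

__all__ = ["LengthSchedule", "LossBreakdown", "pretraining_loss",
           "run_pretraining", "apply_annotation_exclusion"]

CLIP_EPS = 1e-7


@dataclass(frozen=True)
class LengthSchedule:
    """Cycle through encoding lengths, switching every ``switch_every`` steps."""

    lengths: tuple = (128, 512, 1024)
    switch_every: int = 1000

    def __post_init__(self):
        if len(set(self.lengths)) != len(self.lengths) or any(l <= 0 for l in self.lengths):
            raise ValueError("lengths must be positive and distinct")
        if self.switch_every <= 0:
            raise ValueError("switch_every must be positive")

    def length_at(self, step: int) -> int:
        return self.lengths[(step // self.switch_every) % len(self.lengths)]


@dataclass(frozen=True)
class LossBreakdown:
    seq_loss: float
    annot_loss: float

    @property
    def total(self) -> float:
        return self.seq_loss + self.annot_loss


def _loss_tensors(outputs: ModelOutputs, target_tokens: np.ndarray,
                  target_annotations: np.ndarray,
                  pad_mask: np.ndarray | None = None):
    """Differentiable (seq, annot) loss terms, each a scalar Tensor (batch mean)."""
    tok = np.asarray(target_tokens)
    ann = np.asarray(target_annotations, dtype=np.float64)
    probs = outputs.token_probs
    B, L, K = probs.shape
    if tok.shape != (B, L):
        raise ValueError(f"target tokens must have shape {(B, L)}, got {tok.shape}")
    if outputs.annotation_probs.shape != ann.shape:
        raise ValueError("annotation target shape mismatch: "
                         f"{outputs.annotation_probs.shape} vs {ann.shape}")
    onehot = np.zeros((B, L, K))
    onehot[np.arange(B)[:, None], np.arange(L)[None, :], tok] = 1.0
    if pad_mask is not None:
        onehot *= np.asarray(pad_mask, dtype=np.float64)[:, :, None]
    logp = probs.clip(CLIP_EPS, 1.0 - CLIP_EPS).log()
    seq = -(logp * Tensor(onehot)).sum(axis=(1, 2)).mean()
    a = outputs.annotation_probs.clip(CLIP_EPS, 1.0 - CLIP_EPS)
    bce = Tensor(ann) * a.log() + Tensor(1.0 - ann) * (1.0 - a).log()
    annot = -bce.sum(axis=-1).mean()
    return seq, annot


def pretraining_loss(outputs: ModelOutputs, target_tokens: np.ndarray,
                     target_annotations: np.ndarray,
                     pad_mask: np.ndarray | None = None) -> LossBreakdown:
    """Summed-per-example, batch-averaged dual loss (as plain floats).

    ``pad_mask`` (B, L) of {0,1} optionally excludes positions (e.g. PAD)
    from the sequence term; by default every position counts.
    """
    seq, annot = _loss_tensors(outputs, target_tokens, target_annotations, pad_mask)
    return LossBreakdown(seq_loss=seq.item(), annot_loss=annot.item())


def apply_annotation_exclusion(records, excluded_ids):
    """Strip annotations from records whose protein id is in the exclusion set.

    The exclusion set is precomputed externally (e.g. by a sequence-similarity
    search against benchmark test sets); sequences pass through untouched.
    """
    excluded = set(excluded_ids)
    for pid, seq, annots in records:
        if pid in excluded:
            yield pid, seq, frozenset()
        else:
            yield pid, seq, annots


def run_pretraining(model: ProteinModel, records, annot_vocab, *,
                    corruption: CorruptionConfig | None = None,
                    schedule: LengthSchedule | None = None,
                    steps: int = 1000, batch_size: int = 8,
                    learning_rate: float = 2e-4,
                    seed: int = 0,
                    mask_pad: bool = False,
                    checkpoint_every: int | None = None,
                    checkpoint_path=None,
                    log_every: int | None = None,
                    log_fn=print):
    """Train the denoising objective; returns the per-step loss history.

    ``records`` is a materialized list of (id, sequence, annotation-id set)
    triples.  History rows are (step, length, seq_loss, annot_loss, total).
    """
    corruption = corruption or CorruptionConfig()
    schedule = schedule or LengthSchedule()
    rng = np.random.default_rng(seed)
    stream = example_stream(list(records), corruption, rng, annot_vocab,
                            schedule.length_at, batch_size)
    optimizer = Adam(model.parameters(), lr=learning_rate)
    history: list[tuple] = []
    pad_id = None
    if mask_pad:
        from .vocab import build_token_vocabulary
        pad_id = build_token_vocabulary().pad_id
    for step, target_len, batch in stream:
        if step >= steps:
            break
        in_tok = np.stack([ex.input_tokens for ex in batch])
        in_ann = np.stack([ex.input_annotations for ex in batch])
        tgt_tok = np.stack([ex.target_tokens for ex in batch])
        tgt_ann = np.stack([ex.target_annotations for ex in batch])
        outputs = model.forward(in_tok, in_ann)
        mask = (tgt_tok != pad_id) if pad_id is not None else None
        seq, annot = _loss_tensors(outputs, tgt_tok, tgt_ann, mask)
        total = seq + annot
        if not np.isfinite(total.item()):
            raise FloatingPointError(
                f"non-finite loss at step {step} (seq={seq.item()}, annot={annot.item()})")
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
        history.append((step, target_len, seq.item(), annot.item(), total.item()))
        if log_every and step % log_every == 0:
            log_fn(f"step {step} len {target_len} seq {seq.item():.4f} "
                   f"annot {annot.item():.4f} total {total.item():.4f}")
        if checkpoint_every and checkpoint_path and (step + 1) % checkpoint_every == 0:
            from .inspection import save_checkpoint
            save_checkpoint(model, checkpoint_path)
    if checkpoint_path:
        from .inspection import save_checkpoint
        save_checkpoint(model, checkpoint_path)
    return history


def save_loss_history(history, path) -> None:
    """Write history rows as TSV: step, length, seq_loss, annot_loss, total."""
    with open(path, "w") as fh:
        fh.write("step\tlength\tseq_loss\tannot_loss\ttotal\n")
        for step, length, seq, annot, total in history:
            fh.write(f"{step}\t{length}\t{seq:.6f}\t{annot:.6f}\t{total:.6f}\n")
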