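"""Staged fine-tuning protocol with pluggable task heads.

A newly added dense head reads the backbone's final hidden states — the
per-position local states for residue-level tasks, the global state for
whole-protein tasks — through dropout, with an output activation chosen by
label type (sigmoid / softmax / identity).  Training proceeds in three
stages:

1. the backbone is frozen and only the head trains (up to a capped number of
   epochs, learning-rate reduction on validation plateau, early stopping);
2. all weights are unfrozen and training continues under the same controls;
3. one final epoch at a longer encoding length that covers the longest
   training sequence.

The annotation input is the all-zero "no information" vector in every
fine-tuning forward pass (asserted at run time).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from .autodiff import Tensor, softmax_lastaxis
from .layers import Adam, Dense, Module
from .model import ProteinModel
from .pretraining import CLIP_EPS
from .synthetic import TaskSpec
from .vocab import build_token_vocabulary, encode_sequence

__all__ = ["FinetuneSchedule", "FinetunedModel", "attach_head", "finetune",
           "evaluate", "final_epoch_length"]

_LENGTH_LADDER = (32, 64, 128, 512, 1024, 2048, 4096, 8192, 16384)


@dataclass(frozen=True)
class FinetuneSchedule:
    frozen_epochs_max: int = 40
    unfrozen_epochs_max: int = 40
    final_long_epoch: bool = True
    lr_factor: float = 0.25
    lr_patience: int = 2
    early_stopping_patience: int = 4
    dropout_rate: float = 0.5
    base_length: int = 128
    batch_size: int = 16
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.frozen_epochs_max < 1 or self.unfrozen_epochs_max < 1:
            raise ValueError("epoch caps must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def final_epoch_length(task: TaskSpec) -> int:
    """Smallest ladder length covering the longest training sequence + specials."""
    longest = max(len(seq) for _, seq, _ in task.train) + 2
    for length in _LENGTH_LADDER:
        if length >= longest:
            return length
    return longest


class FinetunedModel(Module):
    """Backbone + task head.  The head output is per-position for local tasks
    and per-sequence for global tasks."""

    def __init__(self, backbone: ProteinModel, task: TaskSpec,
                 rng: np.random.Generator, dropout_rate: float = 0.5):
        if task.label_type == "categorical":
            d_out = task.n_classes
        elif task.label_type in ("binary", "continuous"):
            d_out = 1
        else:  # pragma: no cover - TaskSpec already validates
            raise ValueError(f"unsupported label type {task.label_type!r}")
        d_in = backbone.config.d_local if task.resolution == "local" \
            else backbone.config.d_global
        self.backbone = backbone
        self.head = Dense(d_in, d_out, rng)
        self.task_resolution = task.resolution
        self.task_label_type = task.label_type
        self.dropout_rate = dropout_rate

    def __call__(self, token_ids: np.ndarray, *, training: bool = False,
                 dropout_rng: np.random.Generator | None = None) -> Tensor:
        token_ids = np.asarray(token_ids)
        annotations = np.zeros((token_ids.shape[0], self.backbone.config.n_annotations))
        assert not annotations.any(), "fine-tuning must use the all-zero annotation input"
        local, global_ = self.backbone.hidden_states(token_ids, annotations)
        h = local if self.task_resolution == "local" else global_
        if training and self.dropout_rate > 0.0:
            if dropout_rng is None:
                raise ValueError("training forward pass needs a dropout rng")
            keep = 1.0 - self.dropout_rate
            mask = (dropout_rng.random(h.shape) < keep) / keep
            h = h * Tensor(mask)
        out = self.head(h)
        if self.task_label_type == "binary":
            return out[..., 0].sigmoid()
        if self.task_label_type == "categorical":
            return softmax_lastaxis(out)
        return out[..., 0]


def attach_head(backbone: ProteinModel, task: TaskSpec,
                rng: np.random.Generator | int = 0,
                dropout_rate: float = 0.5) -> FinetunedModel:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return FinetunedModel(backbone, task, rng, dropout_rate)


# ---------------------------------------------------------------- data prep

def _encode_split(split, target_len: int, resolution: str, rng: np.random.Generator):
    """Encode a task split at a fixed length.

    Returns (tokens (N,L), labels, mask (N,L)) where mask marks residue
    positions whose label is inside the encoded window (local tasks only).
    """
    vocab = build_token_vocabulary()
    tokens, labels, masks = [], [], []
    for _, seq, label in split:
        enc = encode_sequence(seq, target_len, rng, vocab)
        tokens.append(enc.token_ids)
        if resolution == "local":
            lab = np.zeros(target_len, dtype=np.int64)
            mask = np.zeros(target_len, dtype=bool)
            n_res = target_len - int(enc.has_start) - int(enc.has_end)
            n_res = min(n_res, len(seq) - enc.window_offset)
            start = 1 if enc.has_start else 0
            window = np.asarray(label)[enc.window_offset:enc.window_offset + n_res]
            lab[start:start + len(window)] = window
            mask[start:start + len(window)] = True
            labels.append(lab)
            masks.append(mask)
        else:
            labels.append(label)
            masks.append(np.zeros(0, dtype=bool))
    return np.stack(tokens), np.asarray(labels), np.stack(masks) if resolution == "local" else None


def _task_loss(model: FinetunedModel, preds: Tensor, labels: np.ndarray,
               mask: np.ndarray | None) -> Tensor:
    lt = model.task_label_type
    if lt == "binary":
        p = preds.clip(CLIP_EPS, 1.0 - CLIP_EPS)
        y = labels.astype(np.float64)
        bce = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
        if mask is not None:
            bce = bce * Tensor(mask.astype(np.float64))
            return -bce.sum() * (1.0 / max(mask.sum(), 1))
        return -bce.mean()
    if lt == "categorical":
        onehot = np.zeros(preds.shape)
        onehot[np.arange(len(labels)), labels] = 1.0
        logp = preds.clip(CLIP_EPS, 1.0 - CLIP_EPS).log()
        return -(logp * Tensor(onehot)).sum(axis=-1).mean()
    diff = preds - Tensor(labels.astype(np.float64))
    return (diff * diff).mean()


def _run_stage(model: FinetunedModel, params, encoded_train, encoded_valid,
               max_epochs: int, schedule: FinetuneSchedule,
               rng: np.random.Generator, lr: float, log: list, stage: str) -> None:
    tokens, labels, mask = encoded_train
    optimizer = Adam(params, lr=lr)
    best_val = np.inf
    since_best = 0
    since_lr_drop = 0
    n = len(tokens)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, schedule.batch_size):
            idx = order[lo:lo + schedule.batch_size]
            preds = model(tokens[idx], training=True, dropout_rng=rng)
            loss = _task_loss(model, preds, labels[idx],
                              mask[idx] if mask is not None else None)
            model.zero_grad()
            loss.backward()
            optimizer.step()
        val = _validation_loss(model, encoded_valid)
        log.append((stage, epoch, optimizer.lr, val))
        if val < best_val - 1e-6:
            best_val = val
            since_best = 0
            since_lr_drop = 0
        else:
            since_best += 1
            since_lr_drop += 1
            if since_lr_drop > schedule.lr_patience:
                optimizer.lr *= schedule.lr_factor
                since_lr_drop = 0
            if since_best > schedule.early_stopping_patience:
                break


def _validation_loss(model: FinetunedModel, encoded_valid) -> float:
    tokens, labels, mask = encoded_valid
    preds = model(tokens, training=False)
    return _task_loss(model, preds, labels, mask).item()


def finetune(model: FinetunedModel, task: TaskSpec,
             schedule: FinetuneSchedule | None = None,
             seed: int = 0) -> list:
    """Run the three-stage protocol in place; returns the stage/epoch log."""
    schedule = schedule or FinetuneSchedule()
    if not task.valid:
        raise ValueError("fine-tuning requires a non-empty validation split")
    rng = np.random.default_rng(seed)
    enc_rng = np.random.default_rng(rng.integers(2**31))
    L = schedule.base_length
    encoded_train = _encode_split(task.train, L, task.resolution, enc_rng)
    encoded_valid = _encode_split(task.valid, L, task.resolution, enc_rng)
    log: list = []
    head_params = model.head.parameters()
    # stage 1: backbone frozen, head only
    _run_stage(model, head_params, encoded_train, encoded_valid,
               schedule.frozen_epochs_max, schedule, rng,
               schedule.learning_rate, log, "frozen")
    # stage 2: everything unfrozen
    _run_stage(model, model.parameters(), encoded_train, encoded_valid,
               schedule.unfrozen_epochs_max, schedule, rng,
               schedule.learning_rate * 0.1, log, "unfrozen")
    # stage 3: one epoch at a longer encoding length
    if schedule.final_long_epoch:
        L_long = max(final_epoch_length(task), L)
        encoded_long = _encode_split(task.train, L_long, task.resolution, enc_rng)
        encoded_valid_long = _encode_split(task.valid, L_long, task.resolution, enc_rng)
        _run_stage(model, model.parameters(), encoded_long, encoded_valid_long,
                   1, schedule, rng, schedule.learning_rate * 0.01, log, "final")
    return log


def evaluate(model: FinetunedModel, task: TaskSpec, metric: str,
             target_len: int | None = None, seed: int = 0) -> float:
    """Score the test split.  Metrics: accuracy, spearman, auc.

    Local tasks pool residue-level predictions across proteins, ignoring PAD
    and positions outside the encoded window.
    """
    if not task.test:
        raise ValueError("evaluation requires a non-empty test split")
    rng = np.random.default_rng(seed)
    L = target_len or final_epoch_length(task)
    tokens, labels, mask = _encode_split(task.test, L, task.resolution, rng)
    preds = model(tokens, training=False).data
    if task.resolution == "local":
        y_true = labels[mask]
        y_pred = preds[mask]
    else:
        y_true = labels
        y_pred = preds
    return compute_metric(y_true, y_pred, metric, task.label_type)


def compute_metric(y_true: np.ndarray, y_pred: np.ndarray, metric: str,
                   label_type: str) -> float:
    """Pure metric kernel on pooled predictions."""
    if metric == "accuracy":
        if label_type == "binary":
            return float(np.mean((y_pred >= 0.5).astype(int) == y_true))
        if label_type == "categorical":
            return float(np.mean(np.argmax(y_pred, axis=-1) == y_true))
        raise ValueError("accuracy requires a binary or categorical task")
    if metric == "spearman":
        if label_type != "continuous":
            raise ValueError("spearman requires a continuous task")
        return float(spearmanr(y_true, y_pred).statistic)
    if metric == "auc":
        if label_type != "binary":
            raise ValueError("AUC requires a binary task")
        return float(roc_auc_score(y_true, y_pred))
    raise ValueError(f"unknown metric {metric!r}")


def weight_fingerprint(model: Module) -> str:
    """SHA-256 over all parameter bytes (stable order) — freeze verification."""
    h = hashlib.sha256()
    for name, p in model.named_parameters().items():
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
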