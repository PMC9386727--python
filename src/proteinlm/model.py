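"""The dual-pathway architecture.

Two representations flow in parallel through a stack of transformer-like
blocks: a local one of shape (B, L, d_local) holding per-residue states
s_1..s_L, and a global one of shape (B, d_global) holding a whole-protein
state x.  Within each block:

1. the local path runs parallel narrow (dilation 1) and wide (dilation 5)
   same-padded convolutions, concatenates them and reduces back to d_local
   with a position-wise dense layer;
2. a broadcast dense layer maps the global state to d_local features and adds
   them at every position (global -> local);
3. multi-head global attention pools the local states into d_global features
   added to the global state (local -> global);
4. the global path runs two dense layers.

Each of the four sub-transformations is wrapped in a residual connection
followed by layer normalization (post-norm).  Hidden activations are GELU.
There are no positional embeddings and no self-attention: position
information comes from the convolutions and the START/END markers, and the
cost of a forward pass grows linearly in L.

Global attention pools L local vectors under a single global query:
q = tanh(W_q x), k_i = tanh(W_k s_i), v_i = GELU(W_v s_i),
z = softmax(<q, k_i> / sqrt(d_key)), y = sum_i z_i v_i.
Each of the n_heads heads has its own W_q (d_key x d_global),
W_k (d_key x d_local) and W_v (d_value x d_local), without biases; head
outputs are concatenated (d_value = d_global / n_heads, so the result adds
directly into the global pathway with no output projection).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, gelu, softmax_lastaxis
from .layers import Conv1d, Dense, Embedding, LayerNorm, Module

__all__ = ["ModelConfig", "GlobalAttentionHead", "MultiHeadGlobalAttention",
           "Block", "ProteinModel", "ModelOutputs", "build_model",
           "count_parameters", "conv_receptive_field"]

VOCAB_SIZE = 26


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; the defaults are the full-size model."""

    d_local: int = 128
    d_global: int = 512
    n_blocks: int = 6
    n_heads: int = 4
    d_key: int = 64
    conv_kernel: int = 9
    narrow_dilation: int = 1
    wide_dilation: int = 5
    vocab_size: int = VOCAB_SIZE
    n_annotations: int = 8943

    def __post_init__(self):
        problems = []
        if self.d_global % self.n_heads != 0:
            problems.append("d_global must be divisible by n_heads")
        if self.conv_kernel % 2 != 1:
            problems.append("conv_kernel must be odd")
        for name in ("d_local", "d_global", "n_blocks", "n_heads", "d_key",
                     "narrow_dilation", "wide_dilation", "n_annotations"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be positive")
        if problems:
            raise ValueError("invalid model config: " + "; ".join(problems))

    @property
    def d_value(self) -> int:
        return self.d_global // self.n_heads

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class ModelOutputs:
    """Per-position token distributions and per-protein annotation probabilities."""

    token_probs: Tensor   # (B, L, vocab_size), rows sum to 1
    annotation_probs: Tensor  # (B, n_annotations), entries in [0, 1]


class GlobalAttentionHead(Module):
    """Single-head global attention: one global query over all L positions."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dk, dg, dl, dv = cfg.d_key, cfg.d_global, cfg.d_local, cfg.d_value
        # stored in the formula convention: rows are output features
        self.Wq = Tensor(rng.normal(0, 1 / np.sqrt(dg), (dk, dg)), requires_grad=True)
        self.Wk = Tensor(rng.normal(0, 1 / np.sqrt(dl), (dk, dl)), requires_grad=True)
        self.Wv = Tensor(rng.normal(0, 1 / np.sqrt(dl), (dv, dl)), requires_grad=True)
        self.scale = 1.0 / np.sqrt(dk)

    def __call__(self, x: Tensor, s: Tensor, return_weights: bool = False):
        """x: (B, d_global); s: (B, L, d_local) -> y: (B, d_value)."""
        if s.shape[1] == 0:
            raise ValueError("global attention requires at least one position")
        q = (x @ self.Wq.transpose()).tanh()            # (B, dk)
        k = (s @ self.Wk.transpose()).tanh()            # (B, L, dk)
        v = gelu(s @ self.Wv.transpose())               # (B, L, dv)
        scores = (k * q.reshape(q.shape[0], 1, -1)).sum(axis=-1) * self.scale  # (B, L)
        z = softmax_lastaxis(scores)                    # (B, L)
        y = (v * z.reshape(z.shape[0], -1, 1)).sum(axis=1)  # (B, dv)
        if return_weights:
            return y, z
        return y


class MultiHeadGlobalAttention(Module):
    """Independent heads concatenated in fixed order -> (B, n_heads * d_value)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.heads = [GlobalAttentionHead(cfg, rng) for _ in range(cfg.n_heads)]

    def __call__(self, x: Tensor, s: Tensor, collect: list | None = None) -> Tensor:
        outs = []
        for head in self.heads:
            y, z = head(x, s, return_weights=True)
            if collect is not None:
                collect.append(z.data.copy())
            outs.append(y)
        return concat(outs, axis=-1)


class Block(Module):
    """One transformer-like block updating both representations."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dl, dg = cfg.d_local, cfg.d_global
        self.conv_narrow = Conv1d(dl, dl, cfg.conv_kernel, cfg.narrow_dilation, rng)
        self.conv_wide = Conv1d(dl, dl, cfg.conv_kernel, cfg.wide_dilation, rng)
        self.local_dense = Dense(2 * dl, dl, rng)
        self.norm_local_conv = LayerNorm(dl)
        self.broadcast = Dense(dg, dl, rng)
        self.norm_local_broadcast = LayerNorm(dl)
        self.attention = MultiHeadGlobalAttention(cfg, rng)
        self.norm_global_attention = LayerNorm(dg)
        self.global_dense1 = Dense(dg, dg, rng)
        self.global_dense2 = Dense(dg, dg, rng)
        self.norm_global_dense = LayerNorm(dg)

    def __call__(self, local: Tensor, global_: Tensor,
                 collect_attention: list | None = None):
        # 1. parallel narrow/wide convolutions, concat, position-wise reduce
        conv = concat([gelu(self.conv_narrow(local)), gelu(self.conv_wide(local))], axis=-1)
        local = self.norm_local_conv(local + self.local_dense(conv))
        # 2. broadcast global -> local (replicated over positions)
        g2l = gelu(self.broadcast(global_))             # (B, d_local)
        local = self.norm_local_broadcast(local + g2l.reshape(g2l.shape[0], 1, -1))
        # 3. global attention local -> global
        att = self.attention(global_, local, collect=collect_attention)
        global_ = self.norm_global_attention(global_ + att)
        # 4. two dense layers on the global path
        ff = self.global_dense2(gelu(self.global_dense1(global_)))
        global_ = self.norm_global_dense(global_ + ff)
        return local, global_


class ProteinModel(Module):
    """Embedding + annotation input layer, block stack, and the two output heads."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.embedding = Embedding(config.vocab_size, config.d_local, rng)
        self.annotation_input = Dense(config.n_annotations, config.d_global, rng)
        self.blocks = [Block(config, rng) for _ in range(config.n_blocks)]
        self.sequence_head = Dense(config.d_local, config.vocab_size, rng)
        self.annotation_head = Dense(config.d_global, config.n_annotations, rng)

    # `config` is not a parameter; Module's attribute scan skips it.

    def hidden_states(self, token_ids: np.ndarray, annotations: np.ndarray,
                      collect_attention: list | None = None):
        """Run the block stack; return final (local, global) representations.

        token_ids: (B, L) ints; annotations: (B, n_annotations) 0/1 floats.
        """
        token_ids = np.asarray(token_ids)
        annotations = np.asarray(annotations, dtype=np.float64)
        if token_ids.ndim != 2:
            raise ValueError("token_ids must be a (batch, length) array")
        if token_ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id out of range for the vocabulary")
        if annotations.shape != (token_ids.shape[0], self.config.n_annotations):
            raise ValueError(
                f"annotations must have shape (batch, {self.config.n_annotations}), "
                f"got {annotations.shape}")
        local = self.embedding(token_ids)
        global_ = gelu(self.annotation_input(Tensor(annotations)))
        for block in self.blocks:
            local, global_ = block(local, global_, collect_attention)
        return local, global_

    def forward(self, token_ids: np.ndarray, annotations: np.ndarray,
                collect_attention: list | None = None) -> ModelOutputs:
        local, global_ = self.hidden_states(token_ids, annotations, collect_attention)
        token_probs = softmax_lastaxis(self.sequence_head(local))
        annotation_probs = self.annotation_head(global_).sigmoid()
        return ModelOutputs(token_probs=token_probs, annotation_probs=annotation_probs)

    __call__ = forward

    def zero_global_coupling(self) -> None:
        """Zero the broadcast layers so the global state cannot reach the
        local path — used for receptive-field probing of the conv pathway."""
        for block in self.blocks:
            block.broadcast.W.data[:] = 0.0
            block.broadcast.b.data[:] = 0.0


def build_model(config: ModelConfig, rng: np.random.Generator | int) -> ProteinModel:
    """Construct a model with fan-in-scaled deterministic initialization."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return ProteinModel(config, rng)


def count_parameters(model: ProteinModel) -> int:
    """Exact number of trainable scalars."""
    return model.count_parameters()


def conv_receptive_field(config: ModelConfig) -> tuple[int, int, int]:
    """(narrow_rf, wide_rf, total_rf) of the local convolutional pathway.

    A single layer spans (kernel-1)*dilation + 1 positions.  The narrow and
    wide convolutions are parallel branches, so each block widens the field
    by the larger branch's reach; after n_blocks blocks the total span is
    1 + n_blocks * (kernel-1) * max(dilations).
    """
    k = config.conv_kernel
    narrow = (k - 1) * config.narrow_dilation + 1
    wide = (k - 1) * config.wide_dilation + 1
    growth = max((k - 1) * config.narrow_dilation, (k - 1) * config.wide_dilation)
    total = 1 + config.n_blocks * growth
    return narrow, wide, total
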