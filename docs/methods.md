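# Methods

## Model

`proteinlm` implements a denoising autoencoder for proteins that maintains
two representations in parallel: a **local** tensor of shape
(B, L, d_local) holding one state s_i per residue position, and a **global**
vector of shape (B, d_global) holding one state x per protein.  The two
inputs mirror the two outputs: an integer token sequence (26-symbol
alphabet: the 20 standard amino acids, U, X, OTHER, START, END, PAD) and a
fixed-size multi-hot vector of whole-protein functional annotations.

The stack consists of `n_blocks` transformer-like blocks.  Within each
block, in order, with a residual connection and layer normalization after
each numbered sub-transformation (post-norm):

1. **Local conv sub-block** — narrow (dilation 1) and wide (dilation 5)
   same-padded, stride-1 convolutions of kernel 9 run *in parallel* on the
   block's local input; their GELU outputs are concatenated (2·d_local
   channels) and reduced back to d_local by a position-wise dense layer.
2. **Broadcast** — a dense layer maps the global state to d_local features,
   replicated across all L positions and added into the local path.
3. **Global attention** — `n_heads` independent single-head global-attention
   layers pool the local states into the global path (below).
4. **Global dense sub-block** — two dense layers (GELU between them).

All hidden activations are GELU (exact, erf-based).  There are no positional
embeddings anywhere; position information enters only through the
convolutions and the START/END markers, which is what makes one weight set
valid at any sequence length.

### Global attention

A single head takes the global vector x and the L local vectors s_i and
returns a fixed-size summary:

    q   = tanh(W_q x)            W_q : d_key  × d_global
    k_i = tanh(W_k s_i)          W_k : d_key  × d_local
    v_i = GELU(W_v s_i)          W_v : d_value × d_local
    z   = softmax(⟨q, k_i⟩ / √d_key)
    y   = Σ_i z_i v_i

There is one query per protein, not one per position, so cost and memory are
O(L) rather than the O(L²) of self-attention.  Heads are concatenated in
fixed order; with d_value = d_global / n_heads the concatenation has
dimension d_global and is added residually into the global path with no
output projection (only W_q, W_k, W_v exist).  Score scaling uses √d_key,
the standard attention convention.  Projections carry no bias, matching the
formulas above.

### Receptive fields and parameter budget

A conv layer spans (kernel−1)·dilation+1 positions: 9 for the narrow layer
and 41 for the wide one at the defaults.  Because the two branches are
parallel, each block widens the conv receptive field by
(kernel−1)·max(dilations) = 40, so the default 6-block pathway spans
1 + 6·40 = 241 input positions.  (A sequential narrow→wide topology would
give 289; the parallel topology is what reproduces the architecture's
stated span.)  `conv_receptive_field` computes this analytically and the
tests confirm it by perturbation probing with the broadcast layers zeroed.

At the default configuration (d_local=128, d_global=512, 6 blocks, 4 heads,
d_key=64, 8943 annotations) the model has 16,079,625 trainable scalars
(≈16M), dominated by the annotation input/output layers (≈9.2M) and the six
blocks (≈6.9M).

## Pretraining task

Inputs are corrupted, targets stay clean:

- each token is independently replaced, with probability 0.05, by a token
  drawn uniformly from all 26 (the draw may return the original, so the
  realized change rate is 0.05·25/26);
- each present annotation is dropped with probability 0.25 and each absent
  one switched on with probability 10⁻⁴;
- with probability 0.5 the entire annotation input is blanked to the all-zero
  vector (decided per protein, before per-bit corruption), forcing
  annotation recovery from sequence alone.  Targets are never blanked.

Special-token positions are eligible for replacement corruption by default
(`corrupt_specials=False` exempts them — whether the original scheme
exempted them is not documented, so both are supported).

The loss per example is the literal summed form: categorical cross-entropy
over all L positions plus binary cross-entropy over all annotation bits,
with probabilities clipped to [1e-7, 1−1e-7]; the batch loss is the mean
over examples.  PAD positions are included by default (the model must learn
to predict PAD), with `mask_pad=True` as an option.  Uniform token
predictions therefore give exactly L·ln 26 per example — the baseline the
learning tests must beat.

Proteins longer than the encoding length are windowed: a window is drawn
uniformly from all admissible encodings — START + the first L−1 residues,
the last L−1 residues + END, or any interior window touching neither
terminus — so at least one terminus marker is always absent.  Degenerate
case: when len(seq)+2 barely exceeds the target there may be no room for a
marker at a touched terminus; it is then simply omitted (the "at least one
absent" guarantee still holds).

Encoding length follows a step-count schedule (default lengths
{128, 512, 1024}) rather than wall-clock switching, for reproducibility.
The optimizer is Adam (default learning rate 2e-4 for pretraining) — the
optimizer is exposed entirely through configuration since no particular
choice is intrinsic to the model.  The similarity-based annotation-leakage
filter is implemented as `apply_annotation_exclusion`, which accepts a
precomputed set of protein ids and empties their annotation sets; computing
that set (a BLASTP search) is outside this package's scope.

## Fine-tuning protocol

A new dense head reads the final local states (residue-level tasks) or the
final global state (protein-level tasks) through dropout (default rate 0.5),
with sigmoid / softmax / identity output activation for binary / categorical
/ continuous labels.  The annotation input is the all-zero vector in every
fine-tuning pass (asserted at run time).  Three stages:

1. backbone frozen, head only, up to 40 epochs;
2. everything unfrozen, up to 40 epochs, at 0.1× the stage-1 learning rate
   (a standard precaution so the first unfrozen updates do not destroy the
   pretrained weights);
3. one final epoch at the smallest ladder length (32, 64, 128, 512, 1024,
   2048, ...) covering the longest training sequence plus the two terminus
   markers, at 0.01× the stage-1 rate.

Stages 1–2 each have independent learning-rate-on-plateau (factor 0.25,
patience 2) and early stopping (patience 4) on the validation loss.
Residue labels that fall outside an encoded window are excluded from loss
and metrics — an unavoidable consequence of fixed-length encoding.
Metrics: accuracy, Spearman's ρ (scipy), ROC AUC (scikit-learn); local
tasks pool residue-level predictions across proteins, ignoring PAD.

## Synthetic data

The generator emulates the *shape* of a pretraining corpus, not real
proteins: i.i.d. uniform background over the 20 standard residues (an
empirical frequency vector can be substituted), lengths uniform on
[40, 80], and short planted motifs, each linked to an annotation id that is
attached exactly when the motif is planted.  Toy tasks reuse the same
motifs — a hydrophobic N-terminal motif labeled per-residue
(signal-peptide-like), k class motifs for categorical labels, and a noisy
motif-copy-count regression — so pretrained conv features genuinely
transfer.  A literal motif-matching oracle scores ≥0.99 on every task,
confirming the signal is recoverable.

What passing these tests shows: the architecture can extract planted local
patterns, pool them globally, and transfer pretrained features under the
staged protocol.  What it does not show: performance on real proteins,
whose statistics (residue composition, homology structure, long-range
dependencies, annotation co-occurrence) the generator deliberately does not
model.

## Numerical and engineering choices

- The network runs on a compact reverse-mode automatic-differentiation
  engine written in NumPy (float64), gradient-checked against central
  finite differences at 1e-7 absolute tolerance.  Convolutions are sums of
  shifted position-wise matmuls, which keeps them inside the primitive set
  and preserves exact same-padding semantics.
- Initialization is fan-in-scaled Gaussian (std 1/√fan_in) from a seeded
  generator; building twice from one seed is bit-identical.
- Softmax subtracts a detached row max; cross-entropies clip probabilities
  at 1e-7.  Layer normalization uses eps 1e-5.
- Checkpoints are single HDF5 files holding the config (JSON attribute) and
  every named weight tensor; loading verifies config and shapes and fails
  loudly on mismatch.
- Demo scale: the learning/transfer tests pretrain a reduced model
  (d_local=32, d_global=64, 2 blocks, 2 heads, d_key=16) for 2000 steps
  (batch 16, lengths {64, 128} switching every 250 steps) on a 5000-record
  corpus — sizes chosen so the whole suite runs on a single CPU in minutes.
  The architecture is identical at every scale; only widths, depth and
  corpus size shrink.

## Known limitations

- No GPU path and no minibatch parallelism; the NumPy engine is intended
  for desk-scale experiments, not corpus-scale pretraining.
- Annotations are an unordered label set; ontology structure (term
  hierarchy, propagation) is out of scope.
- No pairwise (position × position) output head, so contact-style tasks do
  not fit the model's output types.
- The fine-tuning CLI serializes only the backbone; task heads are cheap to
  re-train and are not checkpointed.
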