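"""Token and annotation vocabularies and fixed-length sequence encoding.

The token alphabet has exactly 26 symbols: the 20 standard amino acids in
alphabetical one-letter order, selenocysteine (U), undetermined (X), a
catch-all OTHER for any remaining letter (B, Z, J, ...), and the three
structural markers START, END and PAD.  Ids are the positions in that fixed
order, so id assignment is stable across checkpoints.

Proteins longer than the encoding length are represented by a random
contiguous window; the window omits at least one terminus, and the absence of
the START or END marker is the model's signal that it sees a fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "TokenVocabulary",
    "AnnotationVocabulary",
    "EncodedSequence",
    "build_token_vocabulary",
    "encode_sequence",
    "decode_sequence",
    "encode_annotations",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_SPECIALS = ("U", "X", "OTHER", "START", "END", "PAD")


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijective mapping between the 26 token symbols and ids 0..25."""

    symbols: tuple
    index_of: dict = field(repr=False)

    def __post_init__(self):
        if len(self.symbols) != 26 or len(set(self.symbols)) != 26:
            raise ValueError("token vocabulary must hold exactly 26 distinct symbols")

    def __len__(self) -> int:
        return 26

    @property
    def start_id(self) -> int:
        return self.index_of["START"]

    @property
    def end_id(self) -> int:
        return self.index_of["END"]

    @property
    def pad_id(self) -> int:
        return self.index_of["PAD"]

    @property
    def other_id(self) -> int:
        return self.index_of["OTHER"]

    def encode_char(self, ch: str) -> int:
        """Map one sequence character to its token id (unknowns -> OTHER)."""
        return self.index_of.get(ch.upper(), self.other_id)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.symbols) + "\n")

    @classmethod
    def load(cls, path) -> "TokenVocabulary":
        with open(path) as fh:
            symbols = tuple(line.strip() for line in fh if line.strip())
        return cls(symbols=symbols, index_of={s: i for i, s in enumerate(symbols)})


def build_token_vocabulary() -> TokenVocabulary:
    """The canonical 26-symbol vocabulary (20 residues, U, X, OTHER, START, END, PAD)."""
    symbols = tuple(STANDARD_RESIDUES) + _SPECIALS
    return TokenVocabulary(symbols=symbols, index_of={s: i for i, s in enumerate(symbols)})


@dataclass(frozen=True)
class AnnotationVocabulary:
    """Fixed, ordered list of whole-protein annotation identifiers.

    The default size mirrors the 8943-term functional-annotation vocabulary
    used for large-corpus pretraining; any size works for synthetic corpora.
    """

    ids: tuple

    @classmethod
    def from_ids(cls, ids) -> "AnnotationVocabulary":
        ids = tuple(ids)
        if len(set(ids)) != len(ids):
            raise ValueError("annotation ids must be unique")
        return cls(ids=ids)

    @classmethod
    def of_size(cls, n: int, prefix: str = "ANN") -> "AnnotationVocabulary":
        return cls(ids=tuple(f"{prefix}:{i:07d}" for i in range(n)))

    @property
    def size(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, annotation_id: str) -> int:
        try:
            return self.ids.index(annotation_id)
        except ValueError:
            raise KeyError(annotation_id) from None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.ids) + "\n")

    @classmethod
    def load(cls, path) -> "AnnotationVocabulary":
        with open(path) as fh:
            return cls.from_ids(line.strip() for line in fh if line.strip())


@dataclass(frozen=True)
class EncodedSequence:
    """A fixed-length token-id rendering of (a window of) one protein."""

    token_ids: np.ndarray
    has_start: bool
    has_end: bool
    window_offset: int

    def __len__(self) -> int:
        return len(self.token_ids)


def _admissible_windows(seq_len: int, target_len: int) -> list:
    """All (offset, with_start, with_end) encodings of an over-long protein.

    A window starting at residue 0 carries START; a window ending at the last
    residue carries END when there is room for it; interior windows carry
    neither.  Every admissible encoding fills target_len exactly and lacks at
    least one terminus marker.
    """
    T, L = target_len, seq_len
    windows = []
    if L >= T - 1:
        windows.append((0, True, False))           # START + first T-1 residues
        windows.append((L - (T - 1), False, True))  # last T-1 residues + END
    # interior: T residues, touching neither terminus
    for off in range(1, L - T):
        windows.append((off, False, False))
    return windows


def encode_sequence(seq: str, target_len: int, rng: np.random.Generator,
                    vocab: TokenVocabulary | None = None) -> EncodedSequence:
    """Encode a residue string to exactly ``target_len`` token ids.

    Short proteins become START + residues + END + PAD...; over-long proteins
    get a random admissible window drawn uniformly (``rng`` is consumed only
    in that case).
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    if target_len < 3:
        raise ValueError("target_len must be at least 3")
    vocab = vocab or build_token_vocabulary()
    L = len(seq)
    if L + 2 <= target_len:
        ids = np.full(target_len, vocab.pad_id, dtype=np.int64)
        ids[0] = vocab.start_id
        ids[1:L + 1] = [vocab.encode_char(c) for c in seq]
        ids[L + 1] = vocab.end_id
        return EncodedSequence(ids, has_start=True, has_end=True, window_offset=0)

    windows = _admissible_windows(L, target_len)
    off, with_start, with_end = windows[rng.integers(len(windows))]
    n_res = target_len - int(with_start) - int(with_end)
    ids = np.empty(target_len, dtype=np.int64)
    pos = 0
    if with_start:
        ids[0] = vocab.start_id
        pos = 1
    ids[pos:pos + n_res] = [vocab.encode_char(c) for c in seq[off:off + n_res]]
    if with_end:
        ids[-1] = vocab.end_id
    return EncodedSequence(ids, has_start=with_start, has_end=with_end, window_offset=off)


def decode_sequence(encoded: EncodedSequence | np.ndarray,
                    vocab: TokenVocabulary | None = None) -> str:
    """Recover the residue window (specials stripped, OTHER rendered as 'OTHER')."""
    vocab = vocab or build_token_vocabulary()
    ids = encoded.token_ids if isinstance(encoded, EncodedSequence) else np.asarray(encoded)
    drop = {vocab.start_id, vocab.end_id, vocab.pad_id}
    return "".join(vocab.symbols[i] for i in ids if i not in drop)


def encode_annotations(annotation_ids, vocab: AnnotationVocabulary,
                       strict: bool = False) -> np.ndarray:
    """Multi-hot annotation vector; the all-zero vector means 'no information'."""
    bits = np.zeros(vocab.size, dtype=np.int8)
    lookup = {a: j for j, a in enumerate(vocab.ids)}
    for aid in annotation_ids:
        j = lookup.get(aid)
        if j is None:
            if strict:
                raise KeyError(f"unknown annotation id: {aid!r}")
            warnings.warn(f"dropping unknown annotation id {aid!r}", stacklevel=2)
            continue
        bits[j] = 1
    return bits
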