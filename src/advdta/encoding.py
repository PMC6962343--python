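"""Character-level tokenization and fixed-length encoding of biological sequences.

Proteins and SMILES are both treated as raw character strings: the model
downstream learns directly from text, so the encoding contract is simply a
deterministic map string -> fixed-length integer vector. Index 0 is reserved
for padding; tokens occupy 1..V in lexicographic order; characters never seen
when the vocabulary was built map to a dedicated unknown index V+1, so
held-out sequences with unseen characters remain usable.

Multi-character SMILES atoms (Cl, Br) are split into single characters — a
documented limitation of character-level tokenization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # 20 canonical amino acids

#: default maximum encoded lengths per modality
DEFAULT_MAX_LEN = {"protein": 1000, "smiles": 100}


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token -> index map for one modality.

    Indices are contiguous from 1; 0 is the pad index and ``len(tokens)+1``
    the unknown index, so one-hot encodings need ``len(tokens)+2`` columns.
    """

    modality: str
    token_to_index: dict[str, int]

    pad_index: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("protein", "smiles"):
            raise ValueError(f"unknown modality {self.modality!r}")
        idx = sorted(self.token_to_index.values())
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("token indices must be contiguous starting at 1")

    @property
    def unknown_index(self) -> int:
        return len(self.token_to_index) + 1

    @property
    def n_symbols(self) -> int:
        """Number of one-hot columns: pad + tokens + unknown."""
        return len(self.token_to_index) + 2

    @property
    def index_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_index.items()}

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#modality\t{self.modality}\n")
            for tok, i in self.token_to_index.items():
                fh.write(f"{tok}\t{i}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Vocabulary":
        modality = None
        tokens: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, val = line.split("\t")
                if key == "#modality":
                    modality = val
                else:
                    tokens[key] = int(val)
        if modality is None:
            raise ValueError(f"{path}: missing modality header")
        return cls(modality=modality, token_to_index=tokens)


@dataclass(frozen=True)
class EncodedSequence:
    """A string encoded to exactly ``max_len`` integer indices.

    Positions past ``min(original_length, max_len)`` hold the pad index.
    """

    modality: str
    indices: np.ndarray
    original_length: int

    @property
    def max_len(self) -> int:
        return int(self.indices.shape[0])


def build_vocabulary(sequences: list[str], modality: str) -> Vocabulary:
    """Build the character vocabulary observed in ``sequences``.

    Tokens are assigned indices in lexicographic order, so any permutation of
    the corpus yields an identical vocabulary. A protein vocabulary always
    covers the 20 canonical amino-acid letters, even if some are unobserved.
    """
    if not sequences or any(len(s) == 0 for s in sequences):
        raise ValueError("empty corpus")
    chars = set().union(*(set(s) for s in sequences))
    if modality == "protein":
        chars |= set(PROTEIN_ALPHABET)
    tokens = {c: i for i, c in enumerate(sorted(chars), start=1)}
    return Vocabulary(modality=modality, token_to_index=tokens)


def encode_sequence(seq: str, vocab: Vocabulary, max_len: int | None = None) -> EncodedSequence:
    """Encode a string to a fixed-length index vector (padded or truncated)."""
    if max_len is None:
        max_len = DEFAULT_MAX_LEN[vocab.modality]
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    indices = np.zeros(max_len, dtype=np.int64)
    for i, ch in enumerate(seq[:max_len]):
        indices[i] = vocab.token_to_index.get(ch, vocab.unknown_index)
    return EncodedSequence(modality=vocab.modality, indices=indices,
                           original_length=len(seq))


def one_hot(enc: EncodedSequence, vocab: Vocabulary) -> np.ndarray:
    """One-hot matrix ``[max_len, n_symbols]``; row i is the indicator of
    ``enc.indices[i]`` (column 0 = pad, last column = unknown)."""
    n = vocab.n_symbols
    if enc.indices.min() < 0 or enc.indices.max() >= n:
        raise ValueError("encoded index out of range for vocabulary")
    mat = np.zeros((enc.max_len, n), dtype=np.float32)
    mat[np.arange(enc.max_len), enc.indices] = 1.0
    return mat


def one_hot_batch(encs: list[EncodedSequence], vocab: Vocabulary) -> np.ndarray:
    """Stacked one-hot encodings, shape ``[n, max_len, n_symbols]``."""
    return np.stack([one_hot(e, vocab) for e in encs])


def decode_sequence(enc: EncodedSequence, vocab: Vocabulary,
                    unknown_char: str = "?") -> str:
    """Inverse of :func:`encode_sequence` up to truncation; pads are dropped
    and unknown positions render as ``unknown_char`` (lossy by necessity)."""
    rev = vocab.index_to_token
    out = []
    for i in enc.indices:
        i = int(i)
        if i == vocab.pad_index:
            break
        out.append(rev.get(i, unknown_char) if i != vocab.unknown_index else unknown_char)
    return "".join(out)
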