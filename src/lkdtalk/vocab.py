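"""Vocabulary construction and integer encoding for the embedding layer.

The classifier trains its own embedding table, so the vocabulary is built
from the training corpus itself (no pretrained word vectors).  Index 0 is
reserved for padding and index 1 for unknown tokens; remaining indices are
assigned by descending corpus frequency with lexicographic tie-breaking,
making construction deterministic and independent of input order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from lkdtalk.preprocess import TokenSequence

PAD, UNK = "<pad>", "<unk>"
PAD_INDEX, UNK_INDEX = 0, 1

#: Default encoding cap, above the longest comment seen in practice.
DEFAULT_MAX_LEN = 400


@dataclass
class Vocabulary:
    """Injective token -> index map with PAD=0 and UNK=1 always present."""

    token_to_index: dict[str, int]
    min_count: int = 1

    def __post_init__(self) -> None:
        if self.token_to_index.get(PAD) != PAD_INDEX or self.token_to_index.get(UNK) != UNK_INDEX:
            raise ValueError("vocabulary must map PAD to 0 and UNK to 1")
        indices = sorted(self.token_to_index.values())
        if indices != list(range(len(indices))):
            raise ValueError("vocabulary indices must be contiguous 0..size-1")

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    @property
    def index_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_index.items()}

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def save(self, path: str | Path) -> None:
        """Serialize as a two-column UTF-8 text file (token TAB index)."""
        with Path(path).open("w", encoding="utf-8") as fh:
            for token, idx in sorted(self.token_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{token}\t{idx}\n")

    @classmethod
    def load(cls, path: str | Path, min_count: int = 1) -> "Vocabulary":
        mapping: dict[str, int] = {}
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.rstrip("\n"):
                    continue
                token, idx = line.rstrip("\n").split("\t")
                mapping[token] = int(idx)
        return cls(token_to_index=mapping, min_count=min_count)


def build_vocab(sequences: Iterable[TokenSequence | list[str]], min_count: int = 1) -> Vocabulary:
    """Build a vocabulary from token sequences.

    Every token occurring at least ``min_count`` times qualifies; indices
    start at 2 and follow descending frequency, then lexicographic order.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[str] = Counter()
    for seq in sequences:
        counts.update(list(seq))
    qualifying = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    mapping = {PAD: PAD_INDEX, UNK: UNK_INDEX}
    for i, token in enumerate(qualifying, start=2):
        mapping[token] = i
    return Vocabulary(token_to_index=mapping, min_count=min_count)


def encode(
    sequence: TokenSequence | list[str],
    vocab: Vocabulary,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[int]:
    """Map tokens to indices; unknown tokens become UNK.

    Sequences longer than ``max_len`` are truncated from the end.  No
    padding is added here — batching pads.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens = list(sequence)[:max_len]
    return [vocab.token_to_index.get(t, UNK_INDEX) for t in tokens]


def decode(indices: Iterable[int], vocab: Vocabulary) -> list[str]:
    """Inverse of :func:`encode` for in-vocabulary tokens."""
    rev = vocab.index_to_token
    return [rev[i] for i in indices]
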