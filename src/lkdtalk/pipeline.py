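"""Glue joining the pipeline stages: corpus -> tokens -> encoded dataset.

Convenience functions shared by the command-line interface, the test
suite, and reproduction scripts.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

from lkdtalk.corpus_io import Comment, Label
from lkdtalk.preprocess import CleaningConfig, preprocess_comment
from lkdtalk.vocab import DEFAULT_MAX_LEN, Vocabulary, build_vocab, encode

__all__ = ["prepare_dataset"]


def prepare_dataset(
    comments: Sequence[Comment],
    level: Literal["word", "char_gram"] = "word",
    n: int = 10,
    cleaning: Optional[CleaningConfig] = None,
    vocab: Optional[Vocabulary] = None,
    min_count: int = 1,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[tuple[list[int], int]], Vocabulary, list[Comment]]:
    """Clean, tokenize and integer-encode a labeled corpus.

    Returns ``(dataset, vocab, cleaned_comments)`` where ``dataset`` pairs
    each encoded token sequence with its 0/1 label (1 = related).  When
    ``vocab`` is not supplied it is built from this corpus.
    """
    cleaned, sequences = [], []
    for c in comments:
        if c.gold_label is None:
            raise ValueError(f"comment {c.key} has no gold label")
        out, seq = preprocess_comment(c, cleaning, level=level, n=n)
        cleaned.append(out)
        sequences.append(seq)
    if vocab is None:
        vocab = build_vocab(sequences, min_count=min_count)
    dataset = [
        (encode(seq, vocab, max_len=max_len), 1 if c.gold_label is Label.RELATED else 0)
        for seq, c in zip(sequences, cleaned)
    ]
    return dataset, vocab, cleaned
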