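"""Comment data model, label schemas, and multi-source corpus I/O.

A corpus is a list of :class:`Comment` records drawn from four platforms
(New York Times article comments, Reddit, Twitter, YouTube).  Each comment
carries the raw text, an optional cleaned text, an optional human gold label
(related / not related to living kidney donation), an optional machine
prediction with its probability, and — for human-audited false positives —
one of the eight error-taxonomy categories.

The canonical on-disk format is JSON-lines (one object per line); a CSV
dialect (UTF-8, comma-separated, quoted text fields, header row) is provided
for interchange.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

DECISION_THRESHOLD = 0.5


class Source(str, Enum):
    """Platform a comment was collected from."""

    NYT = "nyt"
    REDDIT = "reddit"
    TWITTER = "twitter"
    YOUTUBE = "youtube"


class Label(str, Enum):
    """Binary class: does the comment concern living kidney donation?"""

    RELATED = "related"
    NOT_RELATED = "not_related"


class ErrorType(str, Enum):
    """False-positive error taxonomy.

    Why an *unrelated* comment was nevertheless predicted *related*:
    it was about deceased donation, a figure of speech ("I'd give a
    kidney"), too ambiguous to judge, entirely irrelevant, about kidney
    stones, about donation policy without personal relevance, about the
    recipient/dialysis/kidney-failure side, or about selling organs.
    """

    DECEASED_DONATION = "deceased_donation"
    FIGURE_OF_SPEECH = "figure_of_speech"
    INSUFFICIENT_INFORMATION = "insufficient_information"
    IRRELEVANT = "irrelevant"
    KIDNEY_STONES = "kidney_stones"
    NON_LKD_POLICIES = "non_lkd_policies"
    RECIPIENT_DIALYSIS_FAILURE = "recipient_dialysis_failure"
    SELLING_OR_MONEY = "selling_or_money"


#: Ordered human decision rules governing the gold label.  These document the
#: annotation protocol; the judgment itself is always human, never automated.
ANNOTATION_CRITERIA: tuple[str, ...] = (
    "exclude comments about organ sales or the illicit organ trade",
    "include comments about cost or finance-related donation policies",
    "judge each comment independently of surrounding thread context",
    "label 'related' only when confident; ambiguity defaults to 'not_related'",
)


@dataclass
class AnnotationCriteria:
    """Machine-readable record of the manual-labeling decision rules."""

    decision_rules: tuple[str, ...] = ANNOTATION_CRITERIA

    def __post_init__(self) -> None:
        if not self.decision_rules:
            raise ValueError("decision_rules must be a nonempty ordered list")


class CorpusFormatError(ValueError):
    """A record in a corpus file could not be parsed or validated."""


@dataclass
class Comment:
    """One comment, raw or enriched by later pipeline stages.

    ``(source, comment_id)`` identifies a comment uniquely within a corpus.
    ``error_type`` may only be set on audited false positives, i.e. comments
    with ``gold_label == NOT_RELATED`` and ``predicted_label == RELATED``.
    """

    source: Source
    comment_id: str
    raw_text: str
    date: Optional[str] = None
    clean_text: Optional[str] = None
    gold_label: Optional[Label] = None
    predicted_label: Optional[Label] = None
    predicted_prob: Optional[float] = None
    error_type: Optional[ErrorType] = None

    def __post_init__(self) -> None:
        self.source = Source(self.source)
        if self.gold_label is not None:
            self.gold_label = Label(self.gold_label)
        if self.predicted_label is not None:
            self.predicted_label = Label(self.predicted_label)
        if self.error_type is not None:
            self.error_type = ErrorType(self.error_type)
        if self.predicted_prob is not None:
            if not 0.0 <= self.predicted_prob <= 1.0:
                raise ValueError(
                    f"predicted_prob must lie in [0, 1], got {self.predicted_prob}"
                )
            implied = (
                Label.RELATED
                if self.predicted_prob >= DECISION_THRESHOLD
                else Label.NOT_RELATED
            )
            if self.predicted_label is None:
                self.predicted_label = implied
            elif self.predicted_label is not implied:
                raise ValueError(
                    f"predicted_label {self.predicted_label.value!r} inconsistent "
                    f"with probability {self.predicted_prob} at the 0.5 threshold"
                )
        if self.error_type is not None:
            if (
                self.gold_label is not Label.NOT_RELATED
                or self.predicted_label is not Label.RELATED
            ):
                raise ValueError(
                    "error_type is a false-positive taxonomy: it requires "
                    "gold_label='not_related' and predicted_label='related'"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.source.value, self.comment_id)


# JSONL/CSV column names, in on-disk order.
_FIELDS = ("source", "id", "date", "text", "clean_text", "label", "pred", "prob", "error_type")


def _comment_to_record(c: Comment) -> dict:
    return {
        "source": c.source.value,
        "id": c.comment_id,
        "date": c.date,
        "text": c.raw_text,
        "clean_text": c.clean_text,
        "label": c.gold_label.value if c.gold_label else None,
        "pred": c.predicted_label.value if c.predicted_label else None,
        "prob": c.predicted_prob,
        "error_type": c.error_type.value if c.error_type else None,
    }


def _record_to_comment(rec: dict, lineno: int) -> Comment:
    missing = [k for k in ("source", "id", "text") if not rec.get(k)]
    if missing:
        raise CorpusFormatError(
            f"line {lineno}: record missing required field(s) {missing}"
        )
    try:
        return Comment(
            source=rec["source"],
            comment_id=str(rec["id"]),
            raw_text=rec["text"],
            date=rec.get("date") or None,
            clean_text=rec.get("clean_text") or None,
            gold_label=rec.get("label") or None,
            predicted_label=rec.get("pred") or None,
            predicted_prob=float(rec["prob"]) if rec.get("prob") not in (None, "") else None,
            error_type=rec.get("error_type") or None,
        )
    except ValueError as exc:
        raise CorpusFormatError(f"line {lineno}: {exc}") from exc


def read_corpus(path: str | Path, format: str = "jsonl") -> list[Comment]:
    """Read a comment corpus, collapsing duplicate ``(source, id)`` keys.

    Duplicates keep the first occurrence; the number removed is logged so
    that reported corpus sizes refer to unique comments.

    Parameters
    ----------
    path
        File to read.
    format
        ``"jsonl"`` (default) or ``"csv"``.

    Raises
    ------
    CorpusFormatError
        On a malformed record (with its line number) or an unknown source.
    """
    path = Path(path)
    records: list[tuple[int, dict]] = []
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
                records.append((lineno, rec))
    elif format == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, rec in enumerate(reader, start=2):
                records.append((lineno, rec))
    else:
        raise ValueError(f"unknown corpus format {format!r}; expected 'jsonl' or 'csv'")

    seen: dict[tuple[str, str], Comment] = {}
    duplicates = 0
    for lineno, rec in records:
        comment = _record_to_comment(rec, lineno)
        if comment.key in seen:
            duplicates += 1
        else:
            seen[comment.key] = comment
    if duplicates:
        logger.info(
            "read_corpus(%s): %d unique comments, %d duplicate record(s) removed",
            path, len(seen), duplicates,
        )
    return list(seen.values())


def write_corpus(comments: Iterable[Comment], path: str | Path, format: str = "jsonl") -> int:
    """Write a corpus; returns the number of records written.

    The output is readable by :func:`read_corpus` and round-trips every
    field exactly for corpora without duplicate keys.
    """
    path = Path(path)
    comments = list(comments)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for c in comments:
                rec = {k: v for k, v in _comment_to_record(c).items() if v is not None}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            for c in comments:
                rec = _comment_to_record(c)
                writer.writerow({k: ("" if v is None else v) for k, v in rec.items()})
    else:
        raise ValueError(f"unknown corpus format {format!r}; expected 'jsonl' or 'csv'")
    return len(comments)


def corpus_summary(comments: list[Comment]) -> dict:
    """Per-source counts and word-length statistics of the raw text.

    Word counts are whitespace-split token counts of ``raw_text``; the mean
    is reported to one decimal.  An empty corpus yields zero counts with the
    statistics flagged undefined.
    """
    per_source = {s.value: 0 for s in Source}
    lengths: list[int] = []
    for c in comments:
        per_source[c.source.value] += 1
        lengths.append(len(c.raw_text.split()))
    if not comments:
        return {
            "n": 0,
            "per_source": per_source,
            "words_mean": None,
            "words_min": None,
            "words_max": None,
            "undefined": True,
        }
    return {
        "n": len(comments),
        "per_source": per_source,
        "words_mean": round(sum(lengths) / len(lengths), 1),
        "words_min": min(lengths),
        "words_max": max(lengths),
        "undefined": False,
    }


def dataclass_replace(c: Comment, **changes) -> Comment:
    """Copy a comment with selected fields replaced (re-runs validation)."""
    return dataclasses.replace(c, **changes)
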