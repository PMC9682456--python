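"""Text cleaning, normalization and tokenization for comment corpora.

Social-media comments arrive with HTML markup, URLs, emoji, elongated
words ("pleeeease"), contractions, and number-letter tokens ("401k").
The cleaning chain removes that noise and normalizes what remains so the
classifier sees a compact, stemmed, lowercase word stream.

Steps run in a fixed order chosen so contraction expansion still sees the
original apostrophes and stemming sees lowercase words:

1. strip noise (HTML tags, URLs, emoji, odd symbols, digit+letter tokens)
2. expand contractions ("I've" -> "I have")
3. lowercase
4. collapse character elongations (runs of 3+ identical letters -> 1)
5. drop remaining punctuation
6. whitespace tokenization
7. suffix-stripping stemming ("donating" -> "donat")
8. optional per-word character-gram expansion

Two tokenization levels are supported: whitespace-delimited words, and
fixed-width character grams produced by a sliding window over each word.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from lkdtalk._porter import porter_stem
from lkdtalk.corpus_io import Comment

__all__ = [
    "CleaningConfig",
    "TokenSequence",
    "expand_contractions",
    "collapse_elongations",
    "strip_noise",
    "stem",
    "tokenize_words",
    "tokenize_chars",
    "preprocess_comment",
]


@dataclass
class CleaningConfig:
    """Switches for the individual cleaning steps; all on by default."""

    expand_contractions: bool = True
    strip_html: bool = True
    strip_urls: bool = True
    strip_odd_chars: bool = True
    collapse_elongations: bool = True
    drop_number_letter_combos: bool = True
    strip_emoji: bool = True
    lowercase: bool = True
    stem: bool = True


@dataclass
class TokenSequence:
    """An ordered token list at one tokenization level.

    ``level`` is ``"word"`` for whitespace tokens or ``"char_gram"`` for
    width-``n`` character grams; ``n`` is only meaningful for char grams.
    """

    tokens: list[str]
    level: Literal["word", "char_gram"] = "word"
    n: int | None = None

    def __post_init__(self) -> None:
        if self.level == "char_gram" and (self.n is None or self.n < 1):
            raise ValueError("char_gram sequences require n >= 1")
        for t in self.tokens:
            if any(ch.isspace() for ch in t):
                raise ValueError(f"token {t!r} contains whitespace")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


# ~100-entry contraction dictionary.  Keys are lowercase with a straight
# apostrophe; lookup also matches the typographic apostrophe and any
# capitalization of the first letter.
CONTRACTIONS: dict[str, str] = {
    "ain't": "am not", "aren't": "are not", "can't": "cannot",
    "can't've": "cannot have", "could've": "could have", "couldn't": "could not",
    "didn't": "did not", "doesn't": "does not", "don't": "do not",
    "hadn't": "had not", "hasn't": "has not", "haven't": "have not",
    "he'd": "he would", "he'll": "he will", "he's": "he is",
    "here's": "here is", "how'd": "how did", "how'll": "how will",
    "how's": "how is", "i'd": "i would", "i'll": "i will", "i'm": "i am",
    "i've": "i have", "isn't": "is not", "it'd": "it would",
    "it'll": "it will", "it's": "it is", "let's": "let us",
    "ma'am": "madam", "mightn't": "might not", "might've": "might have",
    "mustn't": "must not", "must've": "must have", "needn't": "need not",
    "o'clock": "of the clock", "oughtn't": "ought not",
    "shan't": "shall not", "she'd": "she would", "she'll": "she will",
    "she's": "she is", "should've": "should have", "shouldn't": "should not",
    "that'd": "that would", "that's": "that is", "there'd": "there would",
    "there's": "there is", "they'd": "they would", "they'll": "they will",
    "they're": "they are", "they've": "they have", "wasn't": "was not",
    "we'd": "we would", "we'll": "we will", "we're": "we are",
    "we've": "we have", "weren't": "were not", "what'll": "what will",
    "what're": "what are", "what's": "what is", "what've": "what have",
    "when's": "when is", "where'd": "where did", "where's": "where is",
    "where've": "where have", "who'll": "who will", "who's": "who is",
    "who've": "who have", "why's": "why is", "won't": "will not",
    "would've": "would have", "wouldn't": "would not", "y'all": "you all",
    "you'd": "you would", "you'll": "you will", "you're": "you are",
    "you've": "you have", "that'll": "that will", "this'll": "this will",
    "there'll": "there will", "it've": "it have", "who'd": "who would",
    "what'd": "what did", "why'd": "why did", "how've": "how have",
    "mayn't": "may not", "daren't": "dare not", "gonna": "going to",
    "gotta": "got to", "wanna": "want to", "kinda": "kind of",
    "sorta": "sort of", "outta": "out of", "lotta": "lot of",
    "'cause": "because", "everybody's": "everybody is",
    "everyone's": "everyone is", "somebody's": "somebody is",
    "someone's": "someone is", "nobody's": "nobody is",
    "something's": "something is", "nothing's": "nothing is",
}

_CONTRACTION_RE = re.compile(
    "|".join(
        re.escape(k).replace("'", "['’]")
        for k in sorted(CONTRACTIONS, key=len, reverse=True)
    ),
    flags=re.IGNORECASE,
)

_URL_RE = re.compile(r"""(?:https?://|www\.)\S+""", re.IGNORECASE)
_HTML_TAG_RE = re.compile(r"</?[a-zA-Z][^<>]*>|<!--.*?-->", re.DOTALL)
_HTML_ENTITY_RE = re.compile(r"&[a-zA-Z]+;|&#\d+;")
_NUM_LETTER_RE = re.compile(r"(?=\S*\d)(?=\S*[a-zA-Z])\S+")
_ELONGATION_RE = re.compile(r"([a-zA-Z])\1{2,}")
_MULTISPACE_RE = re.compile(r"\s+")
# Characters allowed through the odd-character filter: letters, digits,
# whitespace and basic punctuation.
_ODD_CHAR_RE = re.compile(r"""[^A-Za-z0-9\s.,;:!?'"’()\-]""")
_EMOJI_RE = re.compile(
    "["
    "\U0001f000-\U0001faff"  # pictographs, emoticons, symbols
    "\U00002600-\U000027bf"  # misc symbols and dingbats
    "\U0001f1e6-\U0001f1ff"  # regional indicators
    "\U00002190-\U000021ff"  # arrows
    "︎️‍"     # variation selectors, ZWJ
    "]+"
)
_PUNCT_RE = re.compile(r"[^A-Za-z0-9\s]")


def expand_contractions(text: str) -> str:
    """Replace dictionary contractions by their expansions.

    Matching is case-insensitive and accepts both straight and typographic
    apostrophes; the expansion inherits an initial capital.
    """

    def _sub(match: re.Match) -> str:
        found = match.group(0)
        expansion = CONTRACTIONS[found.lower().replace("’", "'")]
        if found[0].isupper():
            return expansion[0].upper() + expansion[1:]
        return expansion

    return _CONTRACTION_RE.sub(_sub, text)


def collapse_elongations(text: str) -> str:
    """Collapse any run of three or more identical letters to one letter."""
    return _ELONGATION_RE.sub(r"\1", text)


def strip_noise(text: str, config: CleaningConfig | None = None) -> str:
    """Remove markup and noise, keeping only plain comment text.

    HTML tags are dropped keeping their inner text; URLs, emoji and odd
    symbols are removed entirely; any token mixing digits and letters
    ("401k") is dropped whole; runs of whitespace are squeezed to one space.
    Pure numbers are kept.
    """
    config = config or CleaningConfig()
    if config.strip_html:
        text = _HTML_TAG_RE.sub(" ", text)
        text = _HTML_ENTITY_RE.sub(" ", text)
    if config.strip_urls:
        text = _URL_RE.sub(" ", text)
    if config.strip_emoji:
        text = _EMOJI_RE.sub(" ", text)
    if config.drop_number_letter_combos:
        text = _NUM_LETTER_RE.sub(" ", text)
    if config.strip_odd_chars:
        text = _ODD_CHAR_RE.sub(" ", text)
    return _MULTISPACE_RE.sub(" ", text).strip()


def stem(tokens: list[str]) -> list[str]:
    """Stem each token by suffix stripping; length-preserving.

    Each token is stemmed to a fixed point (a second pass changes
    nothing), which makes the whole cleaning chain idempotent on its own
    output.  A single pass is not a fixed point for every word — e.g.
    "because" -> "becaus", whose trailing "s" a second pass would strip.
    """
    out = []
    for t in tokens:
        stemmed = porter_stem(t)
        while True:
            again = porter_stem(stemmed)
            if again == stemmed:
                break
            stemmed = again
        out.append(stemmed)
    return out


def tokenize_words(text: str) -> TokenSequence:
    """Split on whitespace into maximal non-space runs."""
    return TokenSequence(tokens=text.split(), level="word")


def tokenize_chars(word: str, n: int) -> list[str]:
    """Width-``n`` character grams of one word (sliding window, stride 1).

    A word of length ``L >= n`` yields ``L - n + 1`` grams; a shorter
    nonempty word falls back to the whole word as a single token; the
    empty word yields no tokens.
    """
    if n < 1:
        raise ValueError(f"char-gram width must be >= 1, got {n}")
    if not word:
        return []
    if len(word) < n:
        return [word]
    return [word[i : i + n] for i in range(len(word) - n + 1)]


def _clean_text(raw: str, config: CleaningConfig) -> str:
    text = strip_noise(raw, config)
    if config.expand_contractions:
        text = expand_contractions(text)
    if config.lowercase:
        text = text.lower()
    if config.collapse_elongations:
        text = collapse_elongations(text)
    # Remaining punctuation (incl. leftover apostrophes) becomes a word break.
    text = _PUNCT_RE.sub(" ", text)
    text = _MULTISPACE_RE.sub(" ", text).strip()
    tokens = text.split()
    if config.stem:
        tokens = stem(tokens)
    return " ".join(tokens)


def preprocess_comment(
    comment: Comment,
    config: CleaningConfig | None = None,
    level: Literal["word", "char_gram"] = "word",
    n: int = 10,
) -> tuple[Comment, TokenSequence]:
    """Clean one comment and tokenize it at the requested level.

    Returns a copy of the comment with ``clean_text`` filled, plus the
    token sequence.  Deterministic, and idempotent at the text level:
    re-running on a comment whose raw text is already clean changes
    nothing.  For ``level="char_gram"`` every cleaned word is expanded
    into its width-``n`` grams (whole word when shorter than ``n``).
    """
    import dataclasses

    config = config or CleaningConfig()
    clean = _clean_text(comment.raw_text, config)
    out = dataclasses.replace(comment, clean_text=clean)
    words = clean.split()
    if level == "word":
        seq = TokenSequence(tokens=words, level="word")
    elif level == "char_gram":
        grams: list[str] = []
        for w in words:
            grams.extend(tokenize_chars(w, n))
        seq = TokenSequence(tokens=grams, level="char_gram", n=n)
    else:
        raise ValueError(f"unknown tokenization level {level!r}")
    return out, seq
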