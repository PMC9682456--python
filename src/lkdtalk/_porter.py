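"""Porter suffix-stripping stemmer.

Classic rule-based stemmer for English: five ordered batches of suffix
rewrite rules gated on the "measure" (the number of vowel-consonant spans)
of the candidate stem.  Maps inflectional variants to a shared stem, e.g.
``donate``, ``donating`` and ``donated`` all become ``donat``.

Only lowercase ASCII words are meaningful inputs; other tokens pass
through unchanged apart from the rules that happen to apply.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Count VC spans: [C](VC)^m[V] — returns m."""
    forms = "".join("c" if _is_cons(stem, i) else "v" for i in range(len(stem)))
    return forms.count("vc")


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """consonant-vowel-consonant, final consonant not w, x or y."""
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, min_measure: int) -> str | None:
    """Rewrite ``suffix`` to ``repl`` if the stem measure is > min_measure."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure:
        return stem + repl
    return word


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        stem = word[:-3]
        return word[:-1] if _measure(stem) > 0 else word
    fired = False
    if word.endswith("ed") and _has_vowel(word[:-2]):
        word, fired = word[:-2], True
    elif word.endswith("ing") and _has_vowel(word[:-3]):
        word, fired = word[:-3], True
    if fired:
        if word.endswith(("at", "bl", "iz")):
            return word + "e"
        if _ends_double_cons(word) and word[-1] not in "lsz":
            return word[:-1]
        if _measure(word) == 1 and _ends_cvc(word):
            return word + "e"
    return word


def _step1c(word: str) -> str:
    # y -> i only after a consonant in a vowel-bearing stem: keeps
    # happy -> happi while leaving kidney, sky, enjoy intact.
    if word.endswith("y"):
        stem = word[:-1]
        if stem and _has_vowel(stem) and _is_cons(stem, len(stem) - 1):
            return stem + "i"
    return word


_STEP2_RULES = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3_RULES = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4_SUFFIXES = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _step2(word: str) -> str:
    for suffix, repl in _STEP2_RULES:
        if word.endswith(suffix):
            out = _replace(word, suffix, repl, 0)
            return out if out is not None else word
    return word


def _step3(word: str) -> str:
    for suffix, repl in _STEP3_RULES:
        if word.endswith(suffix):
            out = _replace(word, suffix, repl, 0)
            return out if out is not None else word
    return word


def _step4(word: str) -> str:
    for suffix in _STEP4_SUFFIXES:
        if word.endswith(suffix):
            stem = word[: len(word) - len(suffix)]
            if suffix == "ion" and (not stem or stem[-1] not in "st"):
                return word
            return stem if _measure(stem) > 1 else word
    return word


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return word


def _step5b(word: str) -> str:
    if word.endswith("ll") and _measure(word) > 1:
        return word[:-1]
    return word


def porter_stem(word: str) -> str:
    """Stem one lowercase word.  Words of length <= 2 pass through."""
    if len(word) <= 2:
        return word
    for step in (_step1a, _step1b, _step1c, _step2, _step3, _step4, _step5a, _step5b):
        word = step(word)
    return word
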