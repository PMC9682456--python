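"""Synthetic multi-source comment corpora for pipeline testing.

Real comment corpora on living kidney donation are not redistributable,
so fixtures are generated: four sources with a realistic source mix,
strong class imbalance (about 5.4% related), right-skewed comment lengths
(mean about 63 words, range 2-380), and the noise artifacts the cleaning
chain must remove (URLs, HTML tags, emoji, elongations, contractions,
number-letter tokens).

Text is a bag of topic words plus filler — statistical structure, not
fluency.  Related comments draw from a living-donation vocabulary;
unrelated comments draw from distractor vocabularies mirroring the
false-positive error taxonomy (deceased-donation talk, "sell a kidney"
figures of speech, kidney stones, policy debate, recipient/dialysis talk,
generic off-topic chatter).  Several distractor words ("kidney", "donor")
deliberately overlap the related vocabulary; ``disjoint_vocabularies``
removes that overlap to produce a cleanly separable corpus for
sanity-checking the classifier.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from lkdtalk.corpus_io import Comment, ErrorType, Label, Source

__all__ = ["GeneratorSpec", "generate_corpus", "shuffle_labels"]


RELATED_VOCAB = [
    "kidney", "donate", "donor", "donation", "transplant", "living",
    "surgery", "recovery", "nephrectomy", "recipient", "match", "organ",
    "altruistic", "evaluation", "hospital", "voucher", "paired", "exchange",
    "laparoscopic", "screening",
]

DISTRACTOR_VOCABS: dict[str, list[str]] = {
    ErrorType.DECEASED_DONATION.value: [
        "deceased", "cadaver", "death", "registry", "license", "harvest",
        "donor", "organ", "list",
    ],
    ErrorType.FIGURE_OF_SPEECH.value: [
        "sell", "kidney", "tickets", "concert", "joke", "literally",
        "swear", "give",
    ],
    ErrorType.INSUFFICIENT_INFORMATION.value: [
        "maybe", "thing", "stuff", "guess", "whatever", "probably",
        "somehow", "anyway",
    ],
    ErrorType.IRRELEVANT.value: [
        "movie", "game", "weather", "music", "celebrity", "video",
        "interview", "politics", "sports", "recipe",
    ],
    ErrorType.KIDNEY_STONES.value: [
        "kidney", "stone", "stones", "pain", "passed", "hurts", "muscle",
    ],
    ErrorType.NON_LKD_POLICIES.value: [
        "policy", "legalize", "market", "law", "government", "opt",
        "system", "incentive", "donation",
    ],
    ErrorType.RECIPIENT_DIALYSIS_FAILURE.value: [
        "dialysis", "failure", "waitlist", "machine", "patient", "kidney",
        "treatment", "clinic",
    ],
    ErrorType.SELLING_OR_MONEY.value: [
        "money", "price", "dollars", "pay", "worth", "cash", "kidney",
        "black",
    ],
}

FILLER_VOCAB = [
    "the", "a", "and", "i", "you", "to", "of", "in", "it", "is", "that",
    "for", "was", "on", "with", "my", "they", "this", "have", "be", "not",
    "are", "but", "at", "we", "so", "what", "all", "would", "there", "when",
    "people", "think", "know", "really", "just", "about", "time", "them",
    "because", "very", "then", "some", "how", "who", "also", "after",
    "never", "always", "said", "years", "made", "good", "want", "more",
    "other", "thanks", "even", "still", "here",
]

_NOISE_URLS = ["http://example.com/page", "https://tinyurl.example/x1", "www.example.org/read"]
_NOISE_EMOJI = ["😀", "😢", "🙏", "❤️", "👍"]
_NOISE_CONTRACTIONS = ["i've", "don't", "can't", "it's", "you're", "won't"]
_NOISE_NUMLETTER = ["401k", "2nd", "5k", "covid19", "b12"]

#: Distractor mix proportional to the published false-positive taxonomy.
_DEFAULT_DISTRACTOR_WEIGHTS = {
    ErrorType.DECEASED_DONATION.value: 27,
    ErrorType.FIGURE_OF_SPEECH.value: 48,
    ErrorType.INSUFFICIENT_INFORMATION.value: 69,
    ErrorType.IRRELEVANT.value: 293,
    ErrorType.KIDNEY_STONES.value: 15,
    ErrorType.NON_LKD_POLICIES.value: 31,
    ErrorType.RECIPIENT_DIALYSIS_FAILURE.value: 76,
    ErrorType.SELLING_OR_MONEY.value: 17,
}


def _normalized(weights: dict[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    return {k: v / total for k, v in weights.items()}


def _default_source_mix() -> dict[str, float]:
    # Proportional to the study's per-source unique-comment counts.
    return _normalized(
        {"twitter": 148662, "reddit": 43382, "nyt": 6559, "youtube": 4616}
    )


def _default_noise_rates() -> dict[str, float]:
    return {
        "url": 0.05,
        "html": 0.05,
        "emoji": 0.10,
        "elongation": 0.05,
        "contraction": 0.30,
        "number_letter": 0.03,
    }


def _default_distractor_mix() -> dict[str, float]:
    return _normalized(dict(_DEFAULT_DISTRACTOR_WEIGHTS))


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic corpus.

    Defaults emulate the study corpus: 5.4% related (11,027 of 203,219),
    source shares proportional to the published per-source counts, word
    counts with mean 63 in [2, 380], and moderate noise rates.
    """

    n: int = 1000
    related_frac: float = 11027 / 203219
    source_mix: dict[str, float] = field(default_factory=_default_source_mix)
    length_mean: float = 63.0
    length_min: int = 2
    length_max: int = 380
    noise_rates: dict[str, float] = field(default_factory=_default_noise_rates)
    distractor_mix: dict[str, float] = field(default_factory=_default_distractor_mix)
    topic_rate: float = 0.4
    disjoint_vocabularies: bool = False
    twitter_word_cap: int | None = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.related_frac <= 1.0:
            raise ValueError("related_frac must lie in [0, 1]")
        if self.length_min > self.length_max:
            raise ValueError("length_min must not exceed length_max")
        if self.length_min < 1:
            raise ValueError("length_min must be >= 1")
        for name, mix in (("source_mix", self.source_mix), ("distractor_mix", self.distractor_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        unknown = set(self.source_mix) - {s.value for s in Source}
        if unknown:
            raise ValueError(f"unknown sources in source_mix: {sorted(unknown)}")
        bad = {k: v for k, v in self.noise_rates.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"noise rates must lie in [0, 1]: {bad}")


def _largest_remainder_allocation(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Integer allocation of ``n`` items matching ``mix`` as closely as possible."""
    keys = sorted(mix)
    raw = {k: n * mix[k] for k in keys}
    alloc = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(alloc.values())
    for k in sorted(keys, key=lambda k: (raw[k] - alloc[k]), reverse=True)[:short]:
        alloc[k] += 1
    return alloc


# Fixed shape of the log-normal length law; gives the heavy right tail
# implied by mean ~63 against max 380.
_LENGTH_SIGMA = 0.85


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _clipped_lognormal_mean(mu: float, sigma: float, a: float, b: float) -> float:
    """Mean of round-free clip(L, a, b) for L ~ LogNormal(mu, sigma)."""
    za = (math.log(a) - mu) / sigma
    zb = (math.log(b) - mu) / sigma
    return (
        a * _norm_cdf(za)
        + b * (1.0 - _norm_cdf(zb))
        + math.exp(mu + sigma**2 / 2) * (_norm_cdf(zb - sigma) - _norm_cdf(za - sigma))
    )


def _solve_mu(target: float, sigma: float, a: float, b: float) -> float:
    """Location parameter whose clipped mean equals ``target`` (bisection)."""
    target = min(max(target, a + 1e-6), b - 1e-6)
    lo, hi = math.log(a) - 5.0, math.log(b) + 5.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _clipped_lognormal_mean(mid, sigma, a, b) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _length_mus(spec: GeneratorSpec) -> tuple[float, float]:
    """(mu for Twitter, mu for other sources).

    Twitter comments are capped at ``twitter_word_cap`` words to mimic the
    platform's character limit; the other sources' location parameter is
    solved so the corpus-wide mixture mean still matches ``length_mean``.
    """
    a, b = float(spec.length_min), float(spec.length_max)
    base_mu = _solve_mu(spec.length_mean, _LENGTH_SIGMA, a, b)
    cap = spec.twitter_word_cap
    p_tw = spec.source_mix.get("twitter", 0.0)
    if cap is None or cap >= b or p_tw == 0.0:
        return base_mu, base_mu
    e_tw = _clipped_lognormal_mean(base_mu, _LENGTH_SIGMA, a, min(cap, b))
    p_rest = 1.0 - p_tw
    if p_rest <= 0.0:
        return base_mu, base_mu
    e_rest = (spec.length_mean - p_tw * e_tw) / p_rest
    return base_mu, _solve_mu(e_rest, _LENGTH_SIGMA, a, b)


def _draw_length(spec: GeneratorSpec, mu: float, upper: int, rng: np.random.Generator) -> int:
    L = int(round(float(rng.lognormal(mu, _LENGTH_SIGMA))))
    return int(np.clip(L, spec.length_min, upper))


def _comment_words(
    vocab: list[str], length: int, topic_rate: float, rng: np.random.Generator
) -> list[str]:
    words = []
    for _ in range(length):
        if vocab and rng.random() < topic_rate:
            words.append(vocab[rng.integers(len(vocab))])
        else:
            words.append(FILLER_VOCAB[rng.integers(len(FILLER_VOCAB))])
    return words


def _inject_noise(words: list[str], rates: dict[str, float], rng: np.random.Generator) -> list[str]:
    words = list(words)

    def insert(token: str) -> None:
        words.insert(int(rng.integers(len(words) + 1)), token)

    if rng.random() < rates.get("url", 0):
        insert(_NOISE_URLS[rng.integers(len(_NOISE_URLS))])
    if rng.random() < rates.get("html", 0) and words:
        i = int(rng.integers(len(words)))
        words[i] = f"<b>{words[i]}</b>"
    if rng.random() < rates.get("emoji", 0):
        insert(_NOISE_EMOJI[rng.integers(len(_NOISE_EMOJI))])
    if rng.random() < rates.get("elongation", 0) and words:
        i = int(rng.integers(len(words)))
        w = words[i]
        if w.isalpha() and w:
            j = int(rng.integers(len(w)))
            words[i] = w[: j + 1] + w[j] * int(rng.integers(2, 5)) + w[j + 1 :]
    if rng.random() < rates.get("contraction", 0):
        insert(_NOISE_CONTRACTIONS[rng.integers(len(_NOISE_CONTRACTIONS))])
    if rng.random() < rates.get("number_letter", 0):
        insert(_NOISE_NUMLETTER[rng.integers(len(_NOISE_NUMLETTER))])
    return words


def generate_corpus(spec: GeneratorSpec) -> list[Comment]:
    """Generate a labeled corpus; deterministic given ``spec.seed``.

    Exactly ``round(n * related_frac)`` comments are related.  Twitter
    comments are additionally capped at 50 words to mimic the platform's
    character limit.
    """
    rng = np.random.default_rng(spec.seed)
    n_related = int(round(spec.n * spec.related_frac))
    labels = np.array([1] * n_related + [0] * (spec.n - n_related))
    rng.shuffle(labels)

    source_alloc = _largest_remainder_allocation(spec.n, spec.source_mix)
    sources: list[str] = []
    for src, count in sorted(source_alloc.items()):
        sources.extend([src] * count)
    rng.shuffle(sources)

    categories = sorted(spec.distractor_mix)
    cat_probs = np.array([spec.distractor_mix[c] for c in categories])

    related_vocab = list(RELATED_VOCAB)
    distractors = {c: list(v) for c, v in DISTRACTOR_VOCABS.items()}
    if spec.disjoint_vocabularies:
        related_set = set(related_vocab)
        distractors = {
            c: [w for w in v if w not in related_set] for c, v in distractors.items()
        }

    mu_twitter, mu_rest = _length_mus(spec)
    cap = spec.twitter_word_cap
    twitter_upper = min(cap, spec.length_max) if cap is not None else spec.length_max

    comments: list[Comment] = []
    for i in range(spec.n):
        src = sources[i]
        if src == "twitter":
            length = _draw_length(spec, mu_twitter, twitter_upper, rng)
        else:
            length = _draw_length(spec, mu_rest, spec.length_max, rng)
        if labels[i] == 1:
            vocab = related_vocab
        else:
            cat = categories[rng.choice(len(categories), p=cat_probs)]
            vocab = distractors[cat]
        words = _comment_words(vocab, length, spec.topic_rate, rng)
        # Noise tokens may lengthen the comment; keep the stated length cap.
        words = _inject_noise(words, spec.noise_rates, rng)[: spec.length_max]
        year = 2010 + int(rng.integers(12))
        month = 1 + int(rng.integers(12))
        day = 1 + int(rng.integers(28))
        comments.append(
            Comment(
                source=Source(src),
                comment_id=f"syn-{i:06d}",
                raw_text=" ".join(words),
                date=f"{year:04d}-{month:02d}-{day:02d}",
                gold_label=Label.RELATED if labels[i] == 1 else Label.NOT_RELATED,
            )
        )
    return comments


def shuffle_labels(corpus: list[Comment], seed: int = 0) -> list[Comment]:
    """Permute gold labels across comments (no-signal control).

    The label multiset is preserved; the pairing of label to text is
    randomized, so any classifier accuracy above chance on the result
    indicates leakage.
    """
    rng = np.random.default_rng(seed)
    labels = [c.gold_label for c in corpus]
    perm = rng.permutation(len(labels))
    return [
        dataclasses.replace(c, gold_label=labels[perm[i]])
        for i, c in enumerate(corpus)
    ]
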