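# Methods

## Problem and model

The task is binary classification of short user comments: is a comment
about living kidney donation (LKD) or not? Comments come from four
platforms (NYT article comments, Reddit, Twitter, YouTube), are written
informally, and the related class is rare (the emulated corpus is ~5.4%
related). The classifier is a recurrent network:

1. an embedding table `E ∈ R^{V×d}` trained jointly with the rest of the
   network (no pretrained vectors — general-purpose embeddings perform
   poorly on this narrow domain);
2. one unidirectional LSTM layer of hidden size `h`, read once over the
   token sequence; the final hidden state summarizes the comment;
3. a two-logit linear output with softmax; the probability of the
   *related* class is thresholded at 0.5 (0.5 itself → related).

Training minimizes cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8). The network, backpropagation through time, and the optimizer
are implemented directly in numpy: at the corpus sizes this package
targets (hundreds to low thousands of comments, hidden sizes ≤ 600) a
framework adds nothing, and a pure-numpy forward/backward pass is
bit-reproducible under a single `numpy` seed across platforms.

### Training controls

- `epochs` (default 30): the returned model carries the weights of the
  epoch with the lowest validation loss (best-epoch selection), so a
  generous epoch budget does not overfit the returned model.
- Mini-batches pad to the longest sequence in the batch with the PAD
  index (0). Padded positions are not masked from the recurrence; the
  PAD embedding is trained like any other row. This is the simplest
  contract, and with best-epoch selection it costs little at these
  sequence lengths.
- Epoch shuffling, weight initialization (uniform ±0.1 embeddings,
  ±1/√fan-in weights, forget-gate bias 1) and everything else downstream
  of `ClassifierConfig.seed` are driven by one `numpy` generator, so
  identical config + data + seed ⇒ identical weights and predictions.
- A single-class training set raises immediately (the loss is
  degenerate); a non-finite loss aborts with a diagnostic rather than
  returning garbage.

### Hyperparameter grid

The explored grid: tokenization level ∈ {word, char_gram}; embedding
size ∈ {500, 600, 700, 1204, 2048}; hidden size ∈ {20, 30, 50, 100, 150,
200, 400, 500, 600}; learning rate ∈ {1e-2 … 1e-6}; batch size ∈ {8, 16,
32, 64, 128}. The value 1204 is kept as published even though it is
plausibly a typo for 1024. Off-grid values (e.g. a 32-dimensional
embedding for smoke tests) require an explicit `allow_off_grid` flag.
Grid points are ranked by mean fold F1, ties broken by mean fold
accuracy, then by the smaller hidden layer.

## Preprocessing

Steps run in a fixed order — noise stripping, contraction expansion,
lowercasing, elongation collapsing, punctuation removal, whitespace
tokenization, stemming, optional character-gram expansion — chosen so
contraction expansion still sees original apostrophes and stemming sees
lowercase words. Decisions worth recording:

- **Stemmer.** A Porter suffix-stripper implemented from the published
  rule set, with one variant: step 1c rewrites a trailing `y` to `i`
  only when preceded by a consonant in a vowel-bearing stem (kidneys →
  kidney, money → money, happy → happi, sky → sky), matching the widely
  used refinement rather than the original rule (which gives kidnei).
- **Fixed-point stemming.** The chain's `stem()` iterates each token
  until stable. One Porter pass is not idempotent (because → becaus,
  whose trailing *s* a second pass strips); iterating to the fixed point
  makes the entire cleaning chain idempotent on its own output, which
  downstream code relies on when re-reading cleaned corpora.
- **Character grams.** Width-`n` sliding windows per word (stride 1, no
  padding); words shorter than `n` fall back to the whole word, so short
  function words are not lost at the winning width of 10. At width 1 the
  word "Medicare" yields its 8 characters.
- **Elongations.** Runs of ≥ 3 identical letters collapse to one —
  reproduces pleeeease → please, and accepts the small risk of mangling
  rare legitimate triples.
- **Number-letter tokens.** A token is dropped iff it mixes digits and
  letters ("401k"); pure numbers survive (ages, years are meaningful).
- **Emoji** are removed outright by Unicode-range matching; **HTML tags**
  are dropped keeping inner text; **URLs** are removed entirely.
- **Contractions** come from a fixed ~100-entry dictionary (both straight
  and typographic apostrophes; "can't" → "cannot").

## Vocabulary and encoding

PAD = 0 and UNK = 1 are always present; other indices follow descending
corpus frequency with lexicographic tie-breaking, making construction
order-independent. `min_count` defaults to 1 (no frequency cutoff).
Encoding truncates from the end at `max_len` = 400 tokens, chosen above
the longest comment the corpus statistics admit (380 words). Word-level
and char-gram runs each build their own vocabulary.

## Experiment design

`make_split` holds out `round_half_up(n × 0.2)` indices as a fixed
validation/test set and deals the remaining indices into K = 10 folds
whose sizes differ by at most one (n = 1174 → holdout 235, folds
94×9 + 93). Splits are not stratified by label or source (a `stratify`
flag exists, off by default). Each fold-model trains on the other nine
folds, uses the holdout for best-epoch selection, and is evaluated on
its fold and on the holdout.

Metric conventions: macro-F1 is the unweighted mean of the two
class-wise F1 scores (the negative class's F1 treats TN as that class's
true positives) — this definition, and not the harmonic mean of
aggregate precision and recall, reproduces the published per-source
macro-F1 values from the published counts. Zero-denominator metrics are
reported as 0 and listed in the report's `degenerate` field.

## Post-classification audit

The assessment layer never computes gold labels: human verdicts
("correct"/"incorrect" per prediction) are ingested from an annotation
CSV and tabulated. Review samples are drawn uniformly within
(source × predicted class), allocating each source's request across the
two predicted classes proportionally while guaranteeing both classes
when both exist.

The module ships the per-source confusion counts of a published
1,824-prediction review together with the published summary percentages
and error-type table, as fixtures for the audit arithmetic.
`audit_reported_metrics` recomputes all metrics from the counts and
flags published cells the counts cannot reproduce — the per-source
accuracy column and the Twitter/YouTube precision–recall cells (which
appear swapped or misprinted). `audit_error_table` does the same for the
error-taxonomy margins, where the published deceased-donation row total
(27) disagrees with its own cells (36) and the YouTube column header
(164) with its cell sum (173); the audit surfaces both without
resolving them.

## Synthetic corpus generator

The generator emulates the statistical shell of the study corpus, not
its language: bag-of-topic-words text with filler, per the defaults —
related fraction 11,027/203,219 ≈ 0.0543; source mix proportional to the
published per-source counts (Twitter 73%, Reddit 21%, NYT 3.2%, YouTube
2.3%); comment lengths log-normal (σ = 0.85, heavy right tail) clipped
to [2, 380] words with corpus-wide mean 63; noise artifacts injected per
comment (URL 5%, HTML 5%, emoji 10%, elongation 5%, contraction 30%,
number-letter token 3%). Twitter comments are capped at 50 words to
mimic the platform's character limit; because Twitter dominates the mix,
the non-Twitter log-normal location is solved by bisection on the
clipped-lognormal mean so the corpus-wide mean still hits the target.

Unrelated comments draw from one of eight distractor vocabularies
mirroring the false-positive taxonomy, mixed in proportion to the
published error-type totals (half "irrelevant"). Several distractor
words ("kidney", "donor", "donation") deliberately overlap the related
vocabulary, as they do in real data; `disjoint_vocabularies=True`
removes the overlap to produce a separable corpus whose only signal is
topical vocabulary.

What passing tests on this generator do and do not show: they verify the
pipeline's mechanics — cleaning, encoding, learning capacity,
determinism, bookkeeping — under controlled signal. They do not show
that the classifier reaches any particular accuracy on real comments,
whose difficulty lives in nuance (figures of speech, policy talk,
ambiguity) that bag-of-words synthesis does not model. The published
84% test accuracy is therefore not a claim this package re-establishes;
its corpus is available only on request from the original authors.

## Scales used in checks

The shipped experiments run at desk scale, chosen for single-CPU
runtimes: separability and control runs use a balanced 500-comment
disjoint-vocabulary corpus (balanced so chance accuracy is 0.5, which
the shuffle control presupposes) with a small configuration (embedding
32, hidden 20, learning rate 1e-3, batch 8, 8 epochs). Under these
conditions nested 10-fold accuracy is ≈ 0.98 and the label-shuffled
control stays within 0.44–0.55 across seeds.

## Known limitations

- The LSTM reads padded tails; very long padding relative to content
  could drift the final state (mitigated by per-batch padding and
  length-bucketed batch scoring).
- Fixed-point stemming is slightly more aggressive than one-pass Porter
  for a few words (please → plea).
- The annotation criteria are shipped as documentation
  (`ANNOTATION_CRITERIA`), not an algorithm: gold labels are always
  human judgments.
- `sample_for_review`'s proportional class allocation is one reasonable
  reading of "random assortment per prediction outcome"; exact per-class
  allocation in the original review is unknown.
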