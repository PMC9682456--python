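# lkdtalk

**lkdtalk** classifies social-media comments as *related* or *not related*
to living kidney donation (LKD). It is aimed at health-services and
transplant-policy researchers who mine public comment streams — New York
Times article comments, Reddit, Twitter, YouTube — to study public
perceptions of and barriers to living donation, where related comments
are a small minority (roughly 5% of a multi-hundred-thousand-comment
corpus) buried in noise.

The package covers the whole workflow:

- **Corpus I/O** — a `Comment` data model (source, id, date, raw/clean
  text, gold label, prediction, false-positive error type) with JSONL and
  CSV readers/writers and duplicate-key collapsing.
- **Preprocessing** — contraction expansion ("I've" → "I have"), HTML /
  URL / emoji / odd-symbol removal, dropping of number-letter tokens
  ("401k"), elongation collapsing ("pleeeease" → "please"), lowercasing,
  suffix-stripping stemming ("donate", "donating", "donated" → "donat"),
  and word-level or character-*n*-gram tokenization.
- **Classifier** — a trainable embedding feeding one LSTM layer whose
  final hidden state feeds a two-logit softmax output; trained with
  cross-entropy and Adam, implemented in numpy, fully deterministic under
  a seed. A probability ≥ 0.5 classifies a comment as related.
- **Evaluation** — nested K-fold validation (20% holdout, K = 10 folds on
  the rest), a hyperparameter grid (tokenization level, embedding size,
  hidden size, learning rate, batch size), and the metric suite

  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R),
  accuracy = (TP+TN)/N, macro-F1 = mean of the two class-wise F1 scores.

- **Assessment** — drawing per-source human-review samples of machine
  predictions, per-source confusion matrices, share tables, and an
  8-category false-positive error taxonomy (deceased donation, figure of
  speech, insufficient information, irrelevant, kidney stones, non-LKD
  policies, recipient/dialysis/kidney failure, selling or money). The
  module also ships the confusion counts of a published 1,824-comment
  post-classification review and an audit that recomputes every summary
  metric from those counts, flagging published cells the counts cannot
  reproduce.
- **Synthetic data** — a generator producing labeled multi-source corpora
  with the study's class imbalance, length distribution, and noise
  artifacts, so the full pipeline is testable without any scraped data.

## Worked example

Generate a balanced, cleanly separable 200-comment corpus, run 5-fold
training with a small configuration, score the corpus, and evaluate:

```bash
lkdtalk simulate --n 200 --related-frac 0.5 --disjoint-vocab --seed 1 --out corpus.jsonl
# wrote 200 comments to corpus.jsonl

cat > config.json <<'JSON'
{"embedding_size": 32, "hidden_size": 20, "learning_rate": 0.001,
 "batch_size": 8, "epochs": 8, "seed": 1, "allow_off_grid": true}
JSON

lkdtalk train --corpus corpus.jsonl --config config.json --k 5 --seed 2 --out run
# mean fold accuracy 0.969, mean fold F1 0.968; checkpoint in run/winner

lkdtalk predict --model run/winner --in corpus.jsonl --out scored.jsonl
lkdtalk evaluate --in scored.jsonl
# {
#   "n": 200,
#   "precision": 0.9346,
#   "recall": 1.0,
#   "f1": 0.9662,
#   "f1_macro": 0.965,
#   "accuracy": 0.965
# }
```

Because the two classes draw from disjoint topic vocabularies, a small
LSTM separates them almost perfectly: mean fold accuracy 0.969 across
the 5 fold-models, and 0.965 accuracy re-scoring the corpus with the
best fold-model. On a label-shuffled copy of the same corpus the same
training recipe stays at chance (≈ 0.5) — the pipeline finds signal only
where signal exists.

The audit side works from counts alone. Feeding the published review's
aggregate confusion counts (TP = 336, FP = 576, FN = 100, TN = 812) to
`compute_metrics` gives precision 36.8%, recall 77.1%, accuracy 62.9%,
macro-F1 60.2%, and `audit_reported_metrics()` marks which published
per-source cells are consistent with their own counts (the per-source
accuracy column and the Twitter/YouTube precision–recall cells are not).

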