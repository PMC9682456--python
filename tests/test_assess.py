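"""Post-classification audit: confusions, shares, error taxonomy."""

import dataclasses

import numpy as np
import pytest

from lkdtalk.assess import (
    PUBLISHED_ERROR_TYPE_COUNTS,
    PUBLISHED_REVIEW_COUNTS,
    AssessmentSample,
    audit_error_table,
    audit_reported_metrics,
    confusion_by_source,
    error_breakdown,
    published_confusions,
    sample_for_review,
    source_share,
)
from lkdtalk.corpus_io import Comment, ErrorType, Label, Source
from lkdtalk.synthetic_data import GeneratorSpec, generate_corpus
from lkdtalk.train_eval import ConfusionCounts


def _reviewed(source, comment_id, predicted, verdict, error_type=None):
    predicted = Label(predicted)
    if verdict == "correct":
        gold = predicted
    else:
        gold = Label.NOT_RELATED if predicted is Label.RELATED else Label.RELATED
    return (
        Comment(
            source=source, comment_id=comment_id, raw_text="-",
            gold_label=gold, predicted_label=predicted, error_type=error_type,
        ),
        verdict,
    )


def _sample(rows):
    comments, verdicts = zip(*rows)
    return AssessmentSample(comments=list(comments), verdicts=list(verdicts))


class TestConfusionBySource:
    def test_aggregate_equals_sum_of_published_sources(self):
        confusions = published_confusions()
        agg = confusions["aggregate"]
        assert (agg.fp, agg.tp, agg.fn, agg.tn) == (576, 336, 100, 812)

    def test_single_source_sample(self):
        sample = _sample([
            _reviewed("nyt", "1", "related", "correct"),
            _reviewed("nyt", "2", "related", "incorrect"),
            _reviewed("nyt", "3", "not_related", "correct"),
            _reviewed("nyt", "4", "not_related", "incorrect"),
        ])
        confusions = confusion_by_source(sample)
        nyt = confusions["nyt"]
        assert (nyt.tp, nyt.fp, nyt.tn, nyt.fn) == (1, 1, 1, 1)
        assert confusions["aggregate"] == dataclasses.replace(nyt, stratum="aggregate")

    def test_aggregate_is_elementwise_sum_random(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(120):
            src = ["nyt", "reddit", "twitter", "youtube"][rng.integers(4)]
            pred = ["related", "not_related"][rng.integers(2)]
            verdict = ["correct", "incorrect"][rng.integers(2)]
            rows.append(_reviewed(src, str(i), pred, verdict))
        confusions = confusion_by_source(_sample(rows))
        total = ConfusionCounts(0, 0, 0, 0)
        for s, cc in confusions.items():
            if s != "aggregate":
                total = total + cc
        assert total == confusions["aggregate"]


@pytest.fixture(scope="module")
def predictions():
    corpus = generate_corpus(GeneratorSpec(n=300, related_frac=0.3, seed=2))
    rng = np.random.default_rng(1)
    return [
        dataclasses.replace(c, gold_label=None, predicted_prob=float(rng.uniform()))
        for c in corpus
    ]


class TestSampleForReview:
    def test_requested_size_and_empty_verdicts(self, predictions):
        n_nyt = sum(1 for c in predictions if c.source is Source.NYT)
        sample = sample_for_review(predictions, {"nyt": min(10, n_nyt)}, seed=4)
        assert len(sample.comments) == min(10, n_nyt)
        assert all(v == "" for v in sample.verdicts)

    def test_deterministic(self, predictions):
        s1 = sample_for_review(predictions, {"reddit": 15}, seed=9)
        s2 = sample_for_review(predictions, {"reddit": 15}, seed=9)
        assert [c.key for c in s1.comments] == [c.key for c in s2.comments]

    def test_both_predicted_classes_present(self, predictions):
        sample = sample_for_review(predictions, {"twitter": 20}, seed=3)
        labels = {c.predicted_label for c in sample.comments}
        assert labels == {Label.RELATED, Label.NOT_RELATED}

    def test_over_request_names_source(self, predictions):
        with pytest.raises(ValueError, match="youtube"):
            sample_for_review(predictions, {"youtube": 10_000}, seed=0)


class TestErrorBreakdown:
    def test_fractions(self):
        rows = [
            _reviewed("nyt", "1", "related", "incorrect", "irrelevant"),
            _reviewed("nyt", "2", "related", "incorrect", "irrelevant"),
            _reviewed("reddit", "3", "related", "incorrect", "irrelevant"),
            _reviewed("reddit", "4", "related", "incorrect", "figure_of_speech"),
            _reviewed("nyt", "5", "related", "correct"),
        ]
        breakdown = error_breakdown(_sample(rows))
        fractions = breakdown.category_fractions()
        assert fractions["irrelevant"] == 0.75
        assert fractions["figure_of_speech"] == 0.25

    def test_no_false_positives_is_valid(self):
        breakdown = error_breakdown(_sample([_reviewed("nyt", "1", "related", "correct")]))
        assert breakdown.table.values.sum() == 0

    def test_missing_error_type_rejected(self):
        rows = [_reviewed("nyt", "1", "related", "incorrect")]
        with pytest.raises(ValueError, match="missing an error type"):
            error_breakdown(_sample(rows))

    def test_published_cells_column_sums(self):
        sums = PUBLISHED_ERROR_TYPE_COUNTS.sum(axis=0)
        assert sums["nyt"] == 107
        assert sums["reddit"] == 146
        assert sums["twitter"] == 159
        # The published YouTube column header says 164 but its cells sum
        # to 173; the audit must surface this rather than match it.
        assert sums["youtube"] == 173

    def test_audit_flags_inconsistent_margins(self):
        audit = audit_error_table().set_index("margin")
        assert bool(audit.loc["column:nyt", "consistent"])
        assert bool(audit.loc["column:reddit", "consistent"])
        assert bool(audit.loc["column:twitter", "consistent"])
        assert not bool(audit.loc["column:youtube", "consistent"])
        assert not bool(audit.loc["row:deceased_donation", "consistent"])
        assert bool(audit.loc["row:irrelevant", "consistent"])


class TestSourceShare:
    def test_published_shares(self):
        shares = source_share(published_confusions())
        assert shares.loc["nyt", "fp_pct"] == 18.6
        assert shares.loc["youtube", "tp_pct"] == 35.7
        assert shares.loc["nyt", "tp_pct"] == 33.3

    def test_single_source_is_all_hundred(self):
        shares = source_share({"nyt": ConfusionCounts(1, 2, 3, 4, "nyt")})
        for cell in ("fp", "tp", "fn", "tn"):
            assert shares.loc["nyt", f"{cell}_pct"] == 100.0

    def test_columns_sum_to_hundred_within_rounding(self):
        rng = np.random.default_rng(5)
        counts = {
            s.value: ConfusionCounts(*(int(x) for x in rng.integers(1, 200, 4)), s.value)
            for s in Source
        }
        shares = source_share(counts)
        for cell in ("fp", "tp", "fn", "tn"):
            assert abs(shares[f"{cell}_pct"].sum() - 100.0) <= 0.3


class TestMetricAudit:
    def test_consistent_cells_match(self):
        audit = audit_reported_metrics().set_index(["stratum", "metric"])
        for key in [
            ("aggregate", "precision"), ("aggregate", "recall"),
            ("aggregate", "accuracy"), ("aggregate", "f1_macro"),
            ("nyt", "precision"), ("nyt", "recall"), ("nyt", "f1_macro"),
            ("reddit", "precision"), ("reddit", "recall"), ("reddit", "f1_macro"),
            ("twitter", "f1_macro"), ("youtube", "f1_macro"),
        ]:
            assert bool(audit.loc[key, "consistent"]), key

    def test_underivable_cells_flagged(self):
        audit = audit_reported_metrics().set_index(["stratum", "metric"])
        for key in [
            ("nyt", "accuracy"), ("reddit", "accuracy"),
            ("twitter", "accuracy"), ("youtube", "accuracy"),
            ("twitter", "precision"), ("twitter", "recall"),
            ("youtube", "precision"), ("youtube", "recall"),
        ]:
            assert not bool(audit.loc[key, "consistent"]), key
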