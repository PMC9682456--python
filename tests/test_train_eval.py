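"""Split plans, the metric suite, K-fold evaluation and grid search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lkdtalk.model import ClassifierConfig
from lkdtalk.pipeline import prepare_dataset
from lkdtalk.synthetic_data import GeneratorSpec, generate_corpus
from lkdtalk.train_eval import (
    ConfusionCounts,
    compute_metrics,
    confusion_from_predictions,
    grid_search,
    kfold_evaluate,
    make_split,
)


class TestMakeSplit:
    def test_even_case(self):
        plan = make_split(100, holdout_frac=0.2, k=10, seed=0)
        assert len(plan.holdout_indices) == 20
        assert [len(f) for f in plan.folds] == [8] * 10

    def test_study_sized_case(self):
        plan = make_split(1174, holdout_frac=0.2, k=10, seed=0)
        assert len(plan.holdout_indices) == 235
        assert sorted(len(f) for f in plan.folds) == [93] + [94] * 9
        # partition laws by brute force
        everything = set(plan.holdout_indices)
        for f in plan.folds:
            assert not everything & set(f)
            everything |= set(f)
        assert everything == set(range(1174))

    def test_deterministic(self):
        assert make_split(97, 0.2, 5, seed=4) == make_split(97, 0.2, 5, seed=4)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_split(10, holdout_frac=0.5, k=10)

    def test_stratified_preserves_balance_and_partition(self):
        labels = [1] * 30 + [0] * 170
        plan = make_split(200, holdout_frac=0.2, k=5, seed=7,
                          labels=labels, stratify=True)
        holdout = set(plan.holdout_indices)
        folds = [set(f) for f in plan.folds]
        assert len(holdout) == 40
        assert sum(1 for i in holdout if labels[i] == 1) == 6  # 30 * 0.2
        union = set().union(*folds)
        assert not holdout & union and holdout | union == set(range(200))
        for f in folds:
            assert any(labels[i] == 1 for i in f)

    def test_stratify_requires_labels(self):
        with pytest.raises(ValueError, match="labels"):
            make_split(100, stratify=True)

    @given(
        n=st.integers(min_value=30, max_value=800),
        frac=st.floats(min_value=0.05, max_value=0.5),
        k=st.integers(min_value=2, max_value=12),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    @settings(deadline=None, max_examples=150)
    def test_partition_laws(self, n, frac, k, seed):
        try:
            plan = make_split(n, frac, k, seed)
        except ValueError:
            return  # infeasible combination
        holdout = set(plan.holdout_indices)
        fold_indices = [i for f in plan.folds for i in f]
        assert len(fold_indices) == len(set(fold_indices))
        assert not holdout & set(fold_indices)
        assert holdout | set(fold_indices) == set(range(n))
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1


class TestComputeMetrics:
    def test_aggregate_review_counts(self):
        r = compute_metrics(ConfusionCounts(tp=336, fp=576, fn=100, tn=812))
        assert round(r.precision, 3) == 0.368
        assert round(r.recall, 3) == 0.771
        assert round(r.accuracy, 3) == 0.629
        assert round(r.f1_macro, 3) == 0.602

    def test_nyt_review_counts(self):
        r = compute_metrics(ConfusionCounts(tp=112, fp=107, fn=19, tn=200))
        assert round(r.precision, 3) == 0.511
        assert round(r.recall, 3) == 0.855
        assert round(r.f1_macro, 2) == 0.70

    def test_degenerate_all_negative(self):
        r = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert r.precision == 0.0 and "precision" in r.degenerate
        assert r.accuracy == 1.0

    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert (r.precision, r.recall, r.f1, r.f1_macro, r.accuracy) == (1, 1, 1, 1, 1)

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        fn=st.integers(0, 500), tn=st.integers(0, 500),
    )
    @settings(deadline=None, max_examples=200)
    def test_macro_f1_equals_brute_force_class_mean(self, tp, fp, fn, tn):
        r = compute_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        # independent oracle: compute each class's F1 from first principles
        def f1_of(tp_, fp_, fn_):
            p = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
            rec = tp_ / (tp_ + fn_) if tp_ + fn_ else 0.0
            return 2 * p * rec / (p + rec) if p + rec else 0.0

        expected = 0.5 * (f1_of(tp, fp, fn) + f1_of(tn, fn, fp))
        assert r.f1_macro == pytest.approx(expected)
        for value in (r.precision, r.recall, r.accuracy, r.f1, r.f1_macro):
            assert 0.0 <= value <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestConfusionFromPredictions:
    def test_counts(self):
        c = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 1, 0, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)
        assert c.total == 5


class TestKFoldEvaluate:
    def test_one_report_per_fold_and_high_accuracy(self, separable_kfold):
        result, plan = separable_kfold
        assert len(result.fold_reports) == 10
        assert len(result.holdout_reports) == 10
        assert result.mean("accuracy") >= 0.9

    def test_summary_table_shape(self, separable_kfold):
        result, _ = separable_kfold
        summary = result.summary()
        assert set(summary["set"]) == {"fold", "holdout"}
        assert len(summary) == 10  # 5 metrics x 2 sets

    def test_plan_corpus_size_mismatch_rejected(self, separable_kfold, separable_dataset):
        _, plan = separable_kfold
        dataset, vocab = separable_dataset
        config = ClassifierConfig(
            embedding_size=32, hidden_size=20, learning_rate=1e-3,
            batch_size=8, epochs=1, seed=1, allow_off_grid=True,
        )
        with pytest.raises(ValueError, match="plan covers"):
            kfold_evaluate(config, dataset[:-1], plan, vocab_size=vocab.size)


@pytest.fixture(scope="module")
def tiny_setup():
    corpus = generate_corpus(
        GeneratorSpec(n=120, related_frac=0.5, disjoint_vocabularies=True, seed=13)
    )
    dataset, vocab, _ = prepare_dataset(corpus)
    plan = make_split(len(dataset), holdout_frac=0.2, k=3, seed=5)
    return dataset, vocab, plan


class TestGridSearch:
    def test_single_config_wins(self, tiny_setup):
        dataset, vocab, plan = tiny_setup
        cfg = ClassifierConfig(
            embedding_size=16, hidden_size=20, learning_rate=1e-3,
            batch_size=8, epochs=3, seed=1, allow_off_grid=True,
        )
        table, winner = grid_search([cfg], dataset, plan, vocab_size=vocab.size)
        assert winner == cfg and len(table) == 1

    def test_trainable_config_beats_untrainable(self, tiny_setup):
        dataset, vocab, plan = tiny_setup
        good = ClassifierConfig(
            embedding_size=16, hidden_size=20, learning_rate=1e-3,
            batch_size=8, epochs=4, seed=1, allow_off_grid=True,
        )
        frozen = ClassifierConfig(
            embedding_size=16, hidden_size=20, learning_rate=1e-6,
            batch_size=8, epochs=1, seed=1, allow_off_grid=True,
        )
        table, winner = grid_search([frozen, good], dataset, plan, vocab_size=vocab.size)
        assert winner == good
        assert table.iloc[0]["learning_rate"] == 1e-3

    def test_empty_grid_rejected(self, tiny_setup):
        dataset, vocab, plan = tiny_setup
        with pytest.raises(ValueError):
            grid_search([], dataset, plan, vocab_size=vocab.size)
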