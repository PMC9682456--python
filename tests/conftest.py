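import pytest

from lkdtalk.model import ClassifierConfig
from lkdtalk.pipeline import prepare_dataset
from lkdtalk.synthetic_data import GeneratorSpec, generate_corpus
from lkdtalk.train_eval import kfold_evaluate, make_split


@pytest.fixture(scope="session")
def small_config():
    """Small off-grid configuration used for training sanity checks."""
    return ClassifierConfig(
        embedding_size=32,
        hidden_size=20,
        learning_rate=1e-3,
        batch_size=8,
        epochs=8,
        seed=1,
        allow_off_grid=True,
    )


@pytest.fixture(scope="session")
def separable_corpus():
    """Balanced corpus whose classes use disjoint topic vocabularies."""
    spec = GeneratorSpec(n=500, related_frac=0.5, disjoint_vocabularies=True, seed=11)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def separable_dataset(separable_corpus):
    dataset, vocab, _ = prepare_dataset(separable_corpus)
    return dataset, vocab


@pytest.fixture(scope="session")
def separable_kfold(separable_dataset, small_config):
    """Nested 10-fold evaluation of the small config on separable data."""
    dataset, vocab = separable_dataset
    plan = make_split(len(dataset), holdout_frac=0.2, k=10, seed=2)
    result = kfold_evaluate(small_config, dataset, plan, vocab_size=vocab.size)
    return result, plan
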