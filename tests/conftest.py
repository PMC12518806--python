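import numpy as np
import pytest

from dtiforest.synthetic import CorpusSpec, TableSpec, generate_corpus, generate_feature_table


@pytest.fixture(scope="session")
def small_table():
    """50-feature / 5-informative planted-logistic fixture."""
    return generate_feature_table(
        TableSpec(n_samples=800, n_features=50, n_informative=5,
                  effect_size=3.0, seed=1))


@pytest.fixture(scope="session")
def small_corpus():
    spec = CorpusSpec(n_documents=100, n_classes=5, seed=11)
    records, labels = generate_corpus(spec)
    return spec, records, labels


@pytest.fixture(scope="session")
def separable_xy():
    """Tiny binary problem where one feature determines the label."""
    rng = np.random.default_rng(0)
    n = 60
    X = rng.standard_normal((n, 4))
    y = (X[:, 2] > 0).astype(int)
    X[:, 2] = np.where(y == 1, X[:, 2] + 4.0, X[:, 2] - 4.0)
    return X, y
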