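import numpy as np
import pytest

from tweetmine import synthetic


@pytest.fixture(scope="session")
def small_corpus():
    """10-day, ~500-tweet corpus with a x5 spike on day 5."""
    cfg = synthetic.default_config(
        n_days=10, base_rate=50, spike_days=((5, 5.0),), seed=101
    )
    store, truth = synthetic.generate_corpus(cfg)
    return cfg, store, truth


@pytest.fixture(scope="session")
def medium_corpus():
    """~12,000-tweet corpus used for convergence-in-probability checks."""
    cfg = synthetic.default_config(n_days=60, base_rate=200, spike_days=(), seed=202)
    store, truth = synthetic.generate_corpus(cfg)
    return cfg, store, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _featurize_with_truth(cfg, store, truth, per_class_top=10, overall_top=60):
    from tweetmine.features import FeatureSpec, build_vocabulary, featurize_all

    scheme = cfg.scheme()
    texts_by_class = {
        c: [store[i].text for i, cat in truth.items() if cat == c]
        for c in scheme.names
    }
    vocab = build_vocabulary(
        texts_by_class, [t.text for t in store],
        per_class_top=per_class_top, overall_top=overall_top,
    )
    spec = FeatureSpec(vocab)
    ids = sorted(truth)
    X = featurize_all([store[i] for i in ids], spec).X.astype(float)
    y = np.array([scheme.index(truth[i]) for i in ids])
    return X, y, scheme.names, spec


@pytest.fixture(scope="session")
def small_feature_matrix(small_corpus):
    """Featurized small corpus: (X float matrix, y indices, category names)."""
    cfg, store, truth = small_corpus
    X, y, cats, _ = _featurize_with_truth(cfg, store, truth)
    return X, y, cats


@pytest.fixture(scope="session")
def medium_features(medium_corpus):
    """Featurized medium corpus plus a 10,000-vector unlabeled pool:
    (X, y, categories, X_unlabeled)."""
    cfg, store, truth = medium_corpus
    X, y, cats, _ = _featurize_with_truth(
        cfg, store, truth, per_class_top=10, overall_top=80
    )
    U = X[:10_000]
    return X, y, cats, U
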