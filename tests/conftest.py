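import pytest

import scootersurv as ss
from scootersurv.ensemble import build_labeled_corpus
from scootersurv.synthetic import demo_pool_config


@pytest.fixture(scope="session")
def demo_pool():
    """Injury-rich pool emulating the ED notes used for model development."""
    return ss.generate_corpus(demo_pool_config(seed=4))


@pytest.fixture(scope="session")
def labeled_corpus(demo_pool):
    return build_labeled_corpus(demo_pool, seed=4)


@pytest.fixture(scope="session")
def labeled_split(labeled_corpus):
    return ss.split_labeled(labeled_corpus, train_fraction=0.70, seed=4)


@pytest.fixture(scope="session")
def trained_small(labeled_split):
    """A 1 DNN + 1 CNN ensemble trained once and shared across tests."""
    spec = ss.EnsembleSpec(n_dnn=1, n_cnn=1, epochs=4, seed=5)
    return ss.train(ss.build_ensemble(spec), labeled_split[0])


@pytest.fixture(scope="session")
def default_corpus():
    """A mid-size corpus at default generator settings."""
    return ss.generate_corpus(ss.GeneratorConfig(n_notes=2000, seed=7))
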