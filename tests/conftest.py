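import pytest

from nerchem.recognizer import Resources, TrainingConfig, train
from nerchem.synthetic_corpus import (
    GeneratorConfig,
    default_bione_gazetteer,
    default_dictionaries,
    generate_documents,
)


@pytest.fixture(scope="session")
def resources() -> Resources:
    return Resources(
        dictionaries=default_dictionaries(), bio_ne=default_bione_gazetteer()
    )


@pytest.fixture(scope="session")
def train_docs():
    return generate_documents(GeneratorConfig(n_documents=60, random_seed=5))


@pytest.fixture(scope="session")
def heldout_docs():
    return generate_documents(GeneratorConfig(n_documents=30, random_seed=205))


@pytest.fixture(scope="session")
def small_model(train_docs, resources):
    """A recognizer trained once per session on a small synthetic corpus."""
    cfg = TrainingConfig(max_iterations=80, random_seed=5)
    return train(train_docs, cfg, resources)
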