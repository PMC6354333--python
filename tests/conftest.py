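import logging

import pytest

from sdpre import (ModelConfig, SynthConfig, TrainConfig, Vocabulary,
                   example_sentence, generate_corpus, prepare_instances)

logging.getLogger("sdpre").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def example():
    """The worked example sentence and its two-nmod parse."""
    return example_sentence()


@pytest.fixture(scope="session")
def example_instances(example):
    sentence, graph = example
    return prepare_instances([sentence], [graph])


@pytest.fixture(scope="session")
def small_corpus():
    cfg = SynthConfig(n_documents=6, sentences_per_doc=5, seed=5)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_instances(small_corpus):
    sentences, graphs = small_corpus
    return prepare_instances(sentences, graphs)


@pytest.fixture()
def tiny_model_config():
    return ModelConfig(word_dim=8, position_dim=4, deprel_dim=4, hidden=6,
                       dropout_rate=0.0)


@pytest.fixture()
def fast_train_config():
    return TrainConfig(learning_rate=0.02, batch_size=16, max_epochs=3, seed=0)


@pytest.fixture()
def small_vocab(small_instances):
    return Vocabulary.build(small_instances)
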