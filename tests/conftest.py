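import numpy as np
import pytest

import aecurate as ac

TRAIN_SEED = 11
EVAL_SEED = 211


@pytest.fixture(scope="session")
def trained_model():
    """Autoencoder trained on clean simulated spikes, shared across tests."""
    X = ac.make_training_set(12000, seed=TRAIN_SEED)
    model = ac.init_model(seed=TRAIN_SEED)
    model, report = ac.train(model, X[1200:], X[:1200], epochs=20, seed=TRAIN_SEED)
    return model, report


@pytest.fixture(scope="session")
def eval_dataset():
    """Labeled evaluation events from templates unseen during training."""
    return ac.make_event_dataset(5000, seed=EVAL_SEED)


@pytest.fixture(scope="session")
def eval_scores(trained_model, eval_dataset):
    model, _ = trained_model
    X, labels = eval_dataset
    return ac.score_batch(model, X), labels


@pytest.fixture(scope="session")
def template_bank():
    return ac.make_template_bank(12, seed=3)
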