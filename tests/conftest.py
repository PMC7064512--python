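import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gazepred as gp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lang():
    """Small order-2 generative language with fairly peaked conditionals."""
    return gp.make_language(vocab_size=30, order=2, concentration=0.1, seed=1)


@pytest.fixture(scope="session")
def reading_corpus(lang):
    return gp.sample_corpus(lang, n_texts=4, words_per_text=250, seed=2)


@pytest.fixture(scope="session")
def train_corpus(lang):
    return gp.sample_corpus(lang, n_texts=12, words_per_text=800, seed=3)


@pytest.fixture(scope="session")
def freq(train_corpus):
    return gp.FrequencyTable.from_corpus(train_corpus)


@pytest.fixture(scope="session")
def features(reading_corpus, freq):
    return gp.compute_features(reading_corpus, freq)


@pytest.fixture(scope="session")
def true_logit(reading_corpus):
    p = reading_corpus.tokens["true_pred"].to_numpy()
    q = np.clip(p, 1e-6, 1 - 1e-6)
    return np.log(q / (1 - q))
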