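import numpy as np
import pytest

from emgburg import ProtocolConfig, build_dataset, default_class_bank, simulate_corpus


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_protocol():
    # scaled-down protocol: 2 subjects x 6 gestures x 5 trials, 1.2 s trials
    return ProtocolConfig(n_subjects=2, n_trials=5, duration=1.2, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_protocol):
    return simulate_corpus(small_protocol)


@pytest.fixture(scope="session")
def small_k_dataset(small_corpus):
    return build_dataset(small_corpus, "K")


@pytest.fixture(scope="session")
def class_bank():
    return default_class_bank()
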