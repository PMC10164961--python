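import numpy as np
import pytest

from ddimug.model import ModelConfig
from ddimug.synthetic_data import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def tiny_config():
    """Small dimensions so unit tests run in milliseconds; dropout off for
    exact determinism in gradient checks."""
    return ModelConfig(encoder_dim=32, gcn_hidden=16, dropout=0.0, seed=0)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_corpus(
        GeneratorConfig(
            n_sentences=40,
            seed=11,
            plant_filter_patterns={"same_name": 2, "abbreviation": 2, "coordination": 2},
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
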