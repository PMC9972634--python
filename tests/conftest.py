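import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from epiharvest.fixtures import GenerationConfig, generate_corpus
from epiharvest.weak_labeler import bundled_gazetteers, bundled_rules


@pytest.fixture(scope="session")
def gazetteers():
    return bundled_gazetteers()


@pytest.fixture(scope="session")
def rules():
    return bundled_rules()


@pytest.fixture(scope="session")
def small_synthetic():
    """20 canonical-form abstracts (no truncated rates) with gold."""
    config = GenerationConfig(n_abstracts=20, seed=7, incomplete_rate_fraction=0.0)
    return generate_corpus(config)
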