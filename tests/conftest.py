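import pytest
from hypothesis import settings

from micemeta.extraction import default_ruleset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from micemeta.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def small_corpus():
    """200 distractor-free synthetic documents with gold and metadata."""
    cfg = SynthConfig(n_docs=200, seed=42)
    return generate_corpus(cfg)
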