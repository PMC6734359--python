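import logging

import pytest
from hypothesis import settings

from radphen.lexicon import load_lexicon

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

# gold mark-up legitimately contains relations into negated mentions
# (e.g. "rather than new blood"); silence the labeller's advisory warning
logging.getLogger("radphen.phenotype_labelling").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def annotate(lexicon):
    """Annotate raw text with the default pipeline."""
    from radphen.pipeline import annotate_report

    def _annotate(text: str):
        return annotate_report(text, lexicon)

    return _annotate
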