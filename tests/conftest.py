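import pytest

from experia.lexicon import default_lexicon
from experia.synthetic import fig3_review


@pytest.fixture(scope="session")
def shipped_lexicon():
    """The packaged seed lexicon + neighbourhood (read-only)."""
    return default_lexicon()


@pytest.fixture()
def worked_example():
    """The hand-tagged breast-cancer review with its expected opinions."""
    return fig3_review()
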