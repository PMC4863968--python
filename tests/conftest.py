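import pytest

from radicon import fig1_fixtures


@pytest.fixture(scope="session")
def scenarios():
    """The nine worked demonstration scenarios, keyed a-i."""
    return fig1_fixtures()
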