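import pytest

from nutribca import paper_base_case


@pytest.fixture(scope="session")
def base():
    """The packaged 2016 base-case parameter set."""
    return paper_base_case()
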