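import pytest

from trd_cea import default_parameters


@pytest.fixture
def bundle():
    return default_parameters()


@pytest.fixture
def published_equivalent(bundle):
    """Defaults with discounting disabled — the accounting mode in which
    the published 35-year tables reproduce (see docs/methods.md)."""
    import copy

    b = copy.deepcopy(bundle)
    b.settings.annual_discount_rate = 0.0
    return b
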