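import pytest

from apolq.simulate import build_default_pool


@pytest.fixture(scope="session")
def afr_pool():
    return build_default_pool("AFR")


@pytest.fixture(scope="session")
def eur_pool():
    return build_default_pool("EUR")
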