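import pytest

from ampchimera import ScoringScheme, default_barcode_map, make_default_panel


@pytest.fixture(scope="session")
def panel():
    return make_default_panel(1)


@pytest.fixture(scope="session")
def bcmap():
    return default_barcode_map()


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()
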