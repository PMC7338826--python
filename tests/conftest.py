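import pytest

from brainperf import default_cards


@pytest.fixture(scope="session")
def cards():
    return default_cards()


@pytest.fixture(scope="session")
def skx(cards):
    return cards.hw("skx_avx512")


@pytest.fixture(scope="session")
def brunel(cards):
    return cards.model("brunel")


@pytest.fixture(scope="session")
def simplified(cards):
    return cards.model("simplified")


@pytest.fixture(scope="session")
def reconstructed(cards):
    return cards.model("reconstructed")


def round2sf(x: float) -> float:
    """Round to two significant figures (the cards' calibration precision)."""
    return float(f"{x:.1e}")
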