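import numpy as np
import pytest

from phonosfe import AncestralLanguage, PhonemeInventory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def inventory():
    return PhonemeInventory.generated(20, prefix="p")


@pytest.fixture
def ancestor(inventory):
    mask = np.zeros(inventory.nph, dtype=np.uint8)
    mask[[2, 5, 9, 11, 17]] = 1
    return AncestralLanguage("A", mask)
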