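import numpy as np
import pytest

from ordshift import OrdinalScale, TwoArmCounts


@pytest.fixture
def scale3():
    return OrdinalScale(("0", "1", "2"))


@pytest.fixture
def toy3(scale3):
    """The documented 2x3 toy table: control (10,10,10), treatment (15,10,5)."""
    return TwoArmCounts(scale3, [[10, 10, 10], [15, 10, 5]])


@pytest.fixture
def table_2x2():
    """2x2 with closed-form OR = 4: control (10,20), treatment (20,10)."""
    return TwoArmCounts(OrdinalScale(("0", "1")), [[10, 20], [20, 10]])


@pytest.fixture
def identical5():
    scale = OrdinalScale(tuple("01234"))
    return TwoArmCounts(scale, [[8, 12, 10, 6, 14]] * 2)


def random_table(rng, k_range=(2, 7), n_range=(3, 40)):
    k = int(rng.integers(*k_range))
    counts = rng.integers(*n_range, size=(2, k))
    return TwoArmCounts(OrdinalScale(tuple(map(str, range(k)))), counts)
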