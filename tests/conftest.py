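import pytest

from pathdiv import FitnessLandscape


@pytest.fixture
def additive_l2():
    """Exactly additive 2-locus landscape with effects (0.3, 0.1)."""
    return FitnessLandscape({"00": 0.6, "01": 0.7, "10": 0.9, "11": 1.0})


@pytest.fixture
def two_peak_l2():
    """Two local peaks: 00 (global) and 11."""
    return FitnessLandscape({"00": 1.0, "01": 0.2, "10": 0.2, "11": 0.9})


@pytest.fixture
def chain_l2():
    """Hole at 10; every genotype has at most one fitter neighbor."""
    return FitnessLandscape({"00": 0.1, "01": 0.2, "11": 0.3})
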