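import pytest

from kpcontrol import scenario_preset, simulate


@pytest.fixture(scope="session")
def nominal_result():
    """200-day integer-order closed loop, steady-therapy gains."""
    return simulate(scenario_preset("nominal"))


@pytest.fixture(scope="session")
def fast_result():
    """100-day integer-order closed loop, fast-eradication gains."""
    return simulate(scenario_preset("fast"))


@pytest.fixture(scope="session")
def fractional_result():
    """150-day Caputo (q = 0.98) closed loop, fast-eradication gains."""
    return simulate(scenario_preset("fractional"))
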