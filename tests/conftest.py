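import pytest

from chronicsim.scenarios import PRESET_NAMES, compare, preset, run_scenario


@pytest.fixture(scope="session")
def preset_results():
    """The four shipped scenarios, run once at default settings."""
    return {name: run_scenario(preset(name)) for name in PRESET_NAMES}


@pytest.fixture(scope="session")
def comparison_report():
    return compare([preset(name) for name in PRESET_NAMES])


@pytest.fixture(scope="session")
def run4_long():
    """The endogenised scenario extended to a 10-year horizon."""
    return run_scenario(preset("run4"), horizon=10.0)
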