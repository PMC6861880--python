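import pytest

from gestex.lung import Environment, PregnancyParams, solve_maternal_steady_state
from gestex.placenta import PlacentaParams, solve_placenta
from gestex.scenarios import SweepSpec, sweep_dataframe


@pytest.fixture(scope="session")
def baseline_lung():
    """Maternal steady state at 0 ppm, room air, pregnancy defaults."""
    return solve_maternal_steady_state(Environment(), PregnancyParams())


@pytest.fixture(scope="session")
def lung_100ppm():
    return solve_maternal_steady_state(Environment(co_ppm=100.0),
                                       PregnancyParams())


@pytest.fixture(scope="session")
def baseline_placenta(baseline_lung):
    return solve_placenta(baseline_lung.venous, PlacentaParams())


@pytest.fixture(scope="session")
def sweep_df():
    """Full default sweep (0-100 ppm, step 5) as a DataFrame."""
    return sweep_dataframe(SweepSpec())
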