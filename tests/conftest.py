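import pytest
from hypothesis import HealthCheck, settings

import stemsoil as ss

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_stand() -> ss.StandSpec:
    """Canonical six-column stand with literature routing fractions."""
    return ss.build_stand([-55, 27, 55, 100, 150, 300])


@pytest.fixture(scope="session")
def default_scenario() -> ss.DepositionScenario:
    """Between-trees scenario in the net-sink-by-anchor regime."""
    return ss.DepositionScenario(
        load_1983=55.0, input_2013=10.0, output_2013=8.0, delay_years=12
    )


@pytest.fixture(scope="session")
def noiseless_survey() -> ss.SurveyPair:
    """Noiseless default synthetic survey pair (1983 / 2010)."""
    return ss.generate_survey(ss.SyntheticSurveyConfig(seed=7))
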