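import pytest

from cheforecast import fit_che_model, generate_forecasts, generate_gdp_projections, generate_panel
from cheforecast.projection import summarize_growth
from cheforecast.synthetic import default_config


@pytest.fixture(scope="session")
def small_config():
    """A compact study: 42 countries over a decade, moderate noise."""
    return default_config(
        n_countries_per_group={"LIC": 8, "LMIC": 10, "UMIC": 12, "HIC": 12},
        years=(2004, 2013),
        seed=3,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Panel + ground truth + forecasts + GDP runs, generated once."""
    panel, truth = generate_panel(small_config)
    forecasts = generate_forecasts(truth)
    gdp = generate_gdp_projections(truth)
    return panel, truth, forecasts, gdp


@pytest.fixture(scope="session")
def fitted(small_world):
    panel, *_ = small_world
    return fit_che_model(panel)


@pytest.fixture(scope="session")
def growth(small_world):
    *_, gdp = small_world
    return summarize_growth(gdp)
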