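import numpy as np
import pytest

from nutrishock import (
    CutPoint,
    Shock,
    TransitionRates,
    load_scenario,
    make_categories,
)
from nutrishock.datasets import data_path
from nutrishock.growth import HazardAnchor


@pytest.fixture(scope="session")
def ear_cut():
    """The vitamin A EAR cut-point shared by the stratified fixtures."""
    return CutPoint(threshold=500.0, semantics="EAR", nutrient_id="vitamin_a")


@pytest.fixture(scope="session")
def income_drop():
    return Shock(driver="income", pct_change=-15.0)


@pytest.fixture(scope="session")
def quartile_scenario():
    """The packaged stratified vitamin A income-shock scenario."""
    return load_scenario(data_path("vitamin_a_income_shock.yaml"))


@pytest.fixture(scope="session")
def pooled_scenario():
    return load_scenario(data_path("vitamin_a_income_shock_pooled.yaml"))


@pytest.fixture(scope="session")
def anchors():
    """Synthetic hazard anchors at Z-band mid-points, monotone in severity."""
    return [
        HazardAnchor(z_ref=-3.5, hr=6.0),
        HazardAnchor(z_ref=-2.5, hr=2.6),
        HazardAnchor(z_ref=-1.5, hr=1.6),
        HazardAnchor(z_ref=-0.5, hr=1.0),
    ]


@pytest.fixture(scope="session")
def categories():
    return make_categories([1.0, 1.6, 2.6, 6.0])


@pytest.fixture()
def mild_rates():
    return TransitionRates(worsen=0.02, improve=0.03, baseline_mortality=0.001, tenure_steps=2)
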