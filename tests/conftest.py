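import numpy as np
import pandas as pd
import pytest

from svyequity.harmonize import SurveyDesign
from svyequity.simulate import Scenario, draw_survey, generate_population


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """Desk-scale scenario used across tests: 5 strata x 4 PSUs x 200."""
    return Scenario(
        n_strata=5,
        psus_per_stratum=4,
        psu_size=200,
        sampled_psus=2,
        sampled_per_psu=60,
        cycles=("2013-2014", "2015-2016"),
    )


@pytest.fixture(scope="session")
def small_census(small_scenario):
    rng = np.random.default_rng(20230916)
    census, truth = generate_population(small_scenario, rng)
    return census, truth


@pytest.fixture(scope="session")
def small_sample(small_scenario, small_census):
    census, _ = small_census
    rng = np.random.default_rng(42)
    return draw_survey(census, small_scenario, rng)


@pytest.fixture()
def flat_design() -> SurveyDesign:
    return SurveyDesign(weight="weight", stratum="stratum", psu="psu")
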