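import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import batlife as bl

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

warnings.filterwarnings(
    "ignore", message=".*prediction points lie outside.*")


@pytest.fixture(scope="session")
def default_pop():
    """One default-condition simulated study (field-study-scale colonies/years)."""
    return bl.simulate_population(bl.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def tables(default_pop):
    ind = default_pop.individuals_frame()
    ev = default_pop.events_frame()
    traits = bl.compute_traits(ind, ev, study_end_year=default_pop.study_end_year)
    pp = bl.build_person_period(ind, ev, default_pop.census, traits=traits,
                                study_end_year=default_pop.study_end_year)
    return {"ind": ind, "ev": ev, "traits": traits, "pp": pp,
            "pop": default_pop}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
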