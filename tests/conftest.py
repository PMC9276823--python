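import numpy as np
import pandas as pd
import pytest

from predselect.selectivity import fit_population
from predselect.synthdata import (
    PopulationParams,
    RetentionCurve,
    SelectionSpec,
    generate_population,
    sample_consumed,
    sample_net_catch,
)


@pytest.fixture(scope="session")
def pop_params():
    return PopulationParams(n_individuals=3000, seed=11)


@pytest.fixture(scope="session")
def population(pop_params):
    return generate_population(pop_params)


@pytest.fixture(scope="session")
def retention():
    return RetentionCurve(l50=25.0, delta=3.0)


@pytest.fixture(scope="session")
def netted(population, retention):
    return sample_net_catch(population, retention, 40, seed=12)


@pytest.fixture(scope="session")
def pop_model(netted, retention):
    return fit_population(netted, retention)


@pytest.fixture(scope="session")
def consumed_random(population, pop_params):
    return sample_consumed(
        population, SelectionSpec("random"), 30, seed=13, params=pop_params
    )


@pytest.fixture(scope="session")
def consumed_growth(population, pop_params):
    return sample_consumed(
        population,
        SelectionSpec("growth", l50_or_e50=-2.0, width=2.0),
        100,
        seed=14,
        params=pop_params,
    )
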