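import numpy as np
import pandas as pd
import pytest

from relsurv import (
    PopulationLifeTable,
    ScenarioConfig,
    StratumSpec,
    make_lifetable,
)


@pytest.fixture
def flat_table() -> PopulationLifeTable:
    """Uniform q = 0.02 everywhere: one stratum, years 1995-2010, ages 65-95."""
    years = np.arange(1995, 2011)
    ages = np.arange(65, 96)
    q = np.full((1, len(years), len(ages)), 0.02)
    return PopulationLifeTable(strata=("S",), years=years, ages=ages, q=q)


@pytest.fixture
def gompertz_table() -> PopulationLifeTable:
    """Default synthetic Gompertz table, single stratum."""
    return make_lifetable(strata_multipliers={"all": 1.0})


@pytest.fixture
def null_scenario() -> ScenarioConfig:
    """Cohort drawn exactly from the life table: no covariates, factor 1."""
    return ScenarioConfig(
        n=5000,
        entry_year=1996,
        entry_age_probs={a: 0.2 for a in range(70, 75)},
        strata=[StratumSpec("all", 1.0)],
        seed=7,
    )


def toy_cohort() -> pd.DataFrame:
    """Five unweighted records: deaths at 0.5 and 1.5, censor at 2.5, two past 3."""
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(5)],
            "entry_age": 70,
            "entry_year": 1996,
            "follow_up": [0.5, 1.5, 2.5, 3.2, 3.7],
            "event": [1, 1, 0, 0, 0],
            "weight": 1.0,
            "stratum": "S",
        }
    )


@pytest.fixture
def five_records() -> pd.DataFrame:
    return toy_cohort()
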