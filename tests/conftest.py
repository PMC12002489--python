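import numpy as np
import pandas as pd
import pytest

from otostock import synthetic


@pytest.fixture(scope="session")
def population():
    """Default synthetic population (the emulated study conditions)."""
    return synthetic.generate_population(seed=20080501)


@pytest.fixture(scope="session")
def aged_frame(population):
    """Truth-joined flat frame: fish_id, site, sex, age, length, mature."""
    df = population.truth.reset_index().merge(
        population.frame[["fish_id", "fl_cm"]], on="fish_id")
    return df.rename(columns={"true_age": "age", "fl_cm": "length"})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
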