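import numpy as np
import pandas as pd
import pytest

from isoniche.synthetic_data import (
    default_diet_spec,
    default_isotope_spec,
    generate_diet_dataset,
    generate_isotope_dataset,
)


@pytest.fixture(scope="session")
def isotope_table() -> pd.DataFrame:
    """Default synthetic isotope table (study-sized groups)."""
    return generate_isotope_dataset(default_isotope_spec(), seed=42)


@pytest.fixture(scope="session")
def diet_table() -> pd.DataFrame:
    """Default synthetic stomach-content table."""
    return generate_diet_dataset(default_diet_spec(), seed=43)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


SMALL_GRID = {"n_estimators": [100], "max_depth": [3, None], "max_features": [3]}
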