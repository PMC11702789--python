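import math

import numpy as np
import pandas as pd
import pytest

from mammorisk import (CovariateDef, CovariateSchema, ModelSpec, RateTable)


@pytest.fixture
def toy_schema() -> CovariateSchema:
    """Two-covariate schema small enough for hand calculation."""
    return CovariateSchema((
        CovariateDef("smoker", "categorical", ("no", "yes"), "no"),
        CovariateDef("dose", "continuous", reference_value=0.0, unit="g/day"),
    ))


@pytest.fixture
def toy_spec(toy_schema) -> ModelSpec:
    return ModelSpec("over50", toy_schema,
                     {"smoker": {"no": 0.0, "yes": math.log(2.0)},
                      "dose": math.log(1.5)})


@pytest.fixture
def flat_incidence() -> RateTable:
    """Constant 1% annual incidence over ages 40-80."""
    ages = np.arange(40, 81)
    return RateTable(ages, np.full(ages.size, 0.01))


@pytest.fixture
def flat_mortality() -> RateTable:
    ages = np.arange(40, 81)
    return RateTable(ages, np.full(ages.size, 0.02))


@pytest.fixture
def zero_mortality() -> RateTable:
    ages = np.arange(40, 81)
    return RateTable(ages, np.zeros(ages.size))


@pytest.fixture
def toy_reference() -> pd.DataFrame:
    """Four-row reference over the toy schema with explicit weights."""
    return pd.DataFrame({
        "smoker": ["no", "yes", "no", "yes"],
        "dose": [0.0, 0.0, 2.0, 2.0],
        "weight": [2.0, 1.0, 1.0, 1.0],
    })
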