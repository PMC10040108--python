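import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from curecorrect import CureParams, PopulationMortality

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pop():
    """Study population mortality: Weibull scale 88 y, shape 11."""
    return PopulationMortality.weibull(88.0, 11.0)


@pytest.fixture(scope="session")
def flat_pop():
    """Zero-mortality population (expected survival identically 1)."""
    return PopulationMortality.from_table(
        pd.DataFrame({"age": np.arange(0, 121), "hazard": 0.0}))


@pytest.fixture
def breast_params():
    """High-survival scenario truths: pi60=0.7, lambda=0.1, gamma=1.1."""
    return CureParams.from_pi60(0.7, beta=-0.15, lambda_=0.1, gamma_=1.1,
                                delta=0.0, alpha=1.0)


@pytest.fixture
def lung_params():
    """Low-survival scenario truths: pi60=0.1, lambda=0.9, gamma=0.8."""
    return CureParams.from_pi60(0.1, beta=-0.75, lambda_=0.9, gamma_=0.8,
                                delta=-0.3, alpha=1.0)
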