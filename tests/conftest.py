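import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from migraine_cea import LifeTable, default_paper_parameters

settings.register_profile(
    "repro", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def em_params():
    return default_paper_parameters("EM")


@pytest.fixture
def cm_params():
    return default_paper_parameters("CM")


@pytest.fixture
def zero_mortality_lifetable():
    ages = np.arange(30, 121)
    return LifeTable(pd.concat([
        pd.DataFrame({"age": ages, "sex": "F", "qx": 0.0}),
        pd.DataFrame({"age": ages, "sex": "M", "qx": 0.0}),
    ], ignore_index=True))


@pytest.fixture(autouse=True)
def _silence_placeholder_price_warning():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*PLACEHOLDER drug price.*")
        yield
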