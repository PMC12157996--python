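import numpy as np
import pytest

from ecx import datasets, doe
from ecx.config import RunConfig


@pytest.fixture(scope="session")
def hep2c_fit():
    """Saturated fit of the bundled Hep2c run means with the published
    pure-error sum of squares injected (replicates were never printed)."""
    model = doe.FactorialModel.from_dataframe(
        datasets.factorial_design("hep2c"), datasets.FACTORS
    )
    ss, df = datasets.ERROR_SS["hep2c"]
    return model.fit(error_ss=ss, error_df=df)


@pytest.fixture(scope="session")
def hep2c_published():
    """Results object built from the published coefficient table."""
    ss, df = datasets.ERROR_SS["hep2c"]
    return doe.FactorialResults.from_params(
        datasets.POLYNOMIAL_COEFFICIENTS["hep2c"], ss, df, config=RunConfig()
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
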