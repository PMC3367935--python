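import numpy as np
import pytest

from fracosc import FixtureSpec, RosslerParams, generate_fixture
from fracosc.lyapunov import rossler_x_series


@pytest.fixture(scope="session")
def logistic_series():
    return generate_fixture(FixtureSpec("logistic_map", length=3000,
                                        parameters={"x0": 0.2}))


@pytest.fixture(scope="session")
def sinusoid_series():
    return generate_fixture(FixtureSpec("sinusoid", length=3000,
                                        parameters={"period": 50.0}))


@pytest.fixture(scope="session")
def rossler_series():
    """Post-transient x-series of the integer-order benchmark Rössler flow."""
    return rossler_x_series(RosslerParams(alpha=1.0))
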