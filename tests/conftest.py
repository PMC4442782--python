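import numpy as np
import pytest

from skewcost import DGPSpec, Dataset, generate

# the 11 scenario settings of the study design
SCENARIO_GRID = (
    [("lognormal", p) for p in (0.5, 1.0, 1.5, 2.0)]
    + [("gamma", p) for p in (0.5, 1.0, 2.0, 4.0)]
    + [("weibull", p) for p in (0.5, 1.0, 5.0)]
)


@pytest.fixture
def lognormal_data() -> Dataset:
    return generate(DGPSpec("lognormal", 0.5, 1.0, 200), seed=71)


@pytest.fixture
def gamma_data() -> Dataset:
    return generate(DGPSpec("gamma", 2.0, 1.0, 200), seed=72)


@pytest.fixture
def weibull_data() -> Dataset:
    return generate(DGPSpec("weibull", 5.0, 1.0, 300), seed=73)


@pytest.fixture
def perfect_loglinear() -> Dataset:
    """Three points lying exactly on ln y = 0 + 1*x."""
    x = np.array([0.0, 0.5, 1.0])
    return Dataset(x=x, y=np.exp(x))
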