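import numpy as np
import pytest

from lacmem import (
    BASE,
    GLUCOSE,
    LACTOSE,
    MEMORY,
    ModelParameters,
    steady_state,
)


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def glucose_ss(params) -> np.ndarray:
    return steady_state(params, GLUCOSE)


@pytest.fixture(scope="session")
def lactose_ss(params) -> np.ndarray:
    return steady_state(params, LACTOSE)


@pytest.fixture(scope="session")
def sweep_result(params):
    """Shared environmental-duration sweep on a trimmed log grid (session
    scope keeps the acceptance-criterion tests within budget)."""
    from lacmem import default_T_grid, sweep_environmental_duration

    grid = default_T_grid(params, 0.05, 10.0, 21)
    return sweep_environmental_duration(params, grid)
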