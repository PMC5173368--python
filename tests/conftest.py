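import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cavenet import SimulationConfig, simulate_landscape

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_landscape() -> pd.DataFrame:
    """400 caves, defaults, fixed seed (positive spatial field)."""
    return simulate_landscape(SimulationConfig(n_caves=400, seed=5))


@pytest.fixture(scope="session")
def model_landscape() -> pd.DataFrame:
    """2000 caves without a residual spatial field, for model-recovery checks."""
    return simulate_landscape(
        SimulationConfig(n_caves=2000, seed=3, spatial_field_sd=0.0))


@pytest.fixture(scope="session")
def clustered_coords(small_landscape) -> np.ndarray:
    return small_landscape[["x_m", "y_m"]].to_numpy(dtype=float)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
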