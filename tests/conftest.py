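import numpy as np
import pytest

from hazelnet.datagen import (
    INPUT_COLUMNS,
    DesignConfig,
    SurfaceParams,
    generate_design,
    simulate_responses,
)


@pytest.fixture(scope="session")
def default_design():
    return generate_design(DesignConfig())


@pytest.fixture(scope="session")
def default_table(default_design):
    """One simulated default experiment (720 rows, 10 % relative noise)."""
    return simulate_responses(default_design, SurfaceParams(seed=42))


@pytest.fixture(scope="session")
def default_xy(default_table):
    X = default_table[INPUT_COLUMNS].to_numpy(float)
    return X, default_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
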