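import numpy as np
import pytest

from dmcwater.dielectric import DielectricParams
from dmcwater.xsec import (
    Channel,
    ChannelKind,
    CrossSectionTable,
    EnergyLossModel,
)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(12345))


@pytest.fixture
def two_channel_table():
    """Tiny elastic + ionisation table, 5 grid points, all σ > 0 above
    threshold; used throughout the sampling tests."""
    grid = np.array([1.0, 10.0, 40.0, 200.0, 2000.0])
    channels = [
        Channel("elastic", ChannelKind.ELASTIC, 0.0, EnergyLossModel.NONE),
        Channel(
            "ion", ChannelKind.IONISATION, 10.0,
            EnergyLossModel.DIFFERENTIAL_TABLE, 2.0,
        ),
    ]
    sigma = np.array(
        [
            [0.30, 0.20, 0.10, 0.05, 0.01],
            [0.00, 1.00, 4.00, 2.00, 0.50],
        ]
    )
    return CrossSectionTable(grid, channels, sigma)


@pytest.fixture
def zero_table():
    """Valid table whose cross sections are all zero (free transport)."""
    grid = np.array([0.001, 30000.0])
    channels = [
        Channel("elastic", ChannelKind.ELASTIC, 0.0, EnergyLossModel.NONE),
        Channel(
            "ion", ChannelKind.IONISATION, 13.0,
            EnergyLossModel.DIFFERENTIAL_TABLE, 5.0,
        ),
    ]
    return CrossSectionTable(grid, channels, np.zeros((2, 2)))


@pytest.fixture
def constant_eps_params():
    """Time-independent dielectric (pure-Coulomb test bed)."""
    return DielectricParams(
        eps_electronic=1.78, eps_static=1.78, components=()
    )


@pytest.fixture(scope="session")
def default_table():
    from dmcwater.default_table import build_default_table

    return build_default_table()
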