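import numpy as np
import pytest

from spphp.polariton import (
    DEFAULT_SHIFT_SENSITIVITY,
    DEFAULT_SIO2,
    DEFAULT_SYSTEM,
    default_grid,
    reststrahlen_band,
)


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def band():
    return reststrahlen_band(DEFAULT_SIO2)


@pytest.fixture(scope="session")
def system():
    return DEFAULT_SYSTEM


@pytest.fixture(scope="session")
def shift_sensitivity():
    return DEFAULT_SHIFT_SENSITIVITY


@pytest.fixture(scope="session")
def transition(system, band, grid, shift_sensitivity):
    """The default dI--dn transition curve (computed once per session)."""
    from spphp.polariton import delta_I_transition_curve

    return delta_I_transition_curve(
        system, np.linspace(0.0, 0.4, 40), band, grid, shift_sensitivity
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
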