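import numpy as np
import pytest

from nanodox import load_defaults


@pytest.fixture(scope="session")
def defaults():
    return load_defaults()


@pytest.fixture(scope="session")
def forward_traj(defaults):
    """Default forward trajectory, shared by read-only tests."""
    from nanodox import simulate_forward

    return simulate_forward(defaults)


@pytest.fixture(scope="session")
def reverse_traj(defaults):
    """Default reverse trajectory, shared by read-only tests."""
    from nanodox import simulate_reverse

    return simulate_reverse(defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
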