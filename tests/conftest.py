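import numpy as np
import pytest

from ballstick import BallStickParams, make_scheme


@pytest.fixture(scope="session")
def scheme64():
    """Default acquisition: 64 directions at b=2500 s/mm^2 plus one b=0."""
    return make_scheme(64, 2500.0, 1)


@pytest.fixture(scope="session")
def scheme16():
    """Small scheme for fast unit tests."""
    return make_scheme(16, 2500.0, 2)


@pytest.fixture()
def single_fibre_truth():
    return BallStickParams(
        S0=100.0, d=1e-3, f=[0.7], theta=[np.pi / 3], phi=[np.pi / 4]
    )


@pytest.fixture()
def crossing_truth():
    return BallStickParams(
        S0=100.0,
        d=1e-3,
        f=[0.35, 0.35],
        theta=[np.pi / 2, np.pi / 2],
        phi=[0.0, np.pi / 2],
    )
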