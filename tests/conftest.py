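import numpy as np
import pytest

from flowsuvr import (
    DEFAULT_FRAME_SCHEDULE,
    HC_BASELINE,
    InputFunction,
    default_aif_spec,
    generate_input_function,
)


@pytest.fixture(scope="session")
def aif_spec():
    return default_aif_spec()


@pytest.fixture(scope="session")
def input_function(aif_spec):
    """The shipped synthetic input function on its default grid."""
    return generate_input_function(aif_spec)


@pytest.fixture(scope="session")
def frames():
    return DEFAULT_FRAME_SCHEDULE


@pytest.fixture(scope="session")
def constant_input():
    """Constant unit plasma and blood out to 700 min (>= 10/alpha1 for all
    built-in regions), for equilibrium checks."""
    t = np.arange(0.0, 701.0, 0.5)
    plasma = np.full_like(t, 10.0)
    plasma[0] = 0.0
    return InputFunction(times=t, plasma=plasma, blood=np.full_like(t, 10.0))


@pytest.fixture(scope="session")
def hc():
    return HC_BASELINE


def random_valid_rates(rng, n):
    """n random (k2, k3, k4) triples spanning realistic tracer kinetics."""
    k2 = rng.uniform(0.01, 1.0, n)
    k3 = rng.uniform(0.0, 0.5, n)
    k4 = rng.uniform(0.0, 0.3, n)
    return np.column_stack([k2, k3, k4])
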