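import numpy as np
import pytest

from sirtkin import ReactionNetwork
from sirtkin.reference import SIRT1_NAM, SIRT3_ISONAM, SIRT3_NAM


@pytest.fixture
def sirt3_params():
    return SIRT3_NAM


@pytest.fixture
def sirt1_params():
    return SIRT1_NAM


@pytest.fixture
def isonam_params():
    return SIRT3_ISONAM


@pytest.fixture
def example_network():
    return ReactionNetwork(
        kon_nad=1.0, koff_nad=100.0, k_c=50.0, k_rex=200.0,
        kon_nam=2.0, koff_nam=500.0, kcat=0.5, kcat_bound=0.5,
    )


def random_network(rng: np.random.Generator) -> ReactionNetwork:
    """Log-uniform draw of an inhibitable base-exchange network."""
    lo, hi = -1.0, 3.0  # decades around unity for every rate constant
    draw = lambda: float(10.0 ** rng.uniform(lo, hi))
    return ReactionNetwork(
        kon_nad=draw(), koff_nad=draw(), k_c=draw(), k_rex=draw(),
        kon_nam=draw(), koff_nam=draw(),
        kcat=float(10.0 ** rng.uniform(-3.0, 0.0)),
        kcat_bound=float(10.0 ** rng.uniform(-3.0, 0.0)),
    )
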