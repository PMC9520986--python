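import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def warm_numba():
    """Compile the numba kernels once so timings elsewhere are honest."""
    from fractalknots import knots3d

    knots3d.classify_knot(
        knots3d.make_fixture("trefoil", 60), np.random.default_rng(0)
    )
    return True
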