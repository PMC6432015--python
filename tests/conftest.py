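import numpy as np
import pytest

from knotbridge import ChainParameters
from knotbridge.sampler import parametric_knot


@pytest.fixture(scope="session")
def params240():
    """Paper-scale chain: N = 240 beads, Kuhn length 10b (lP = 5b)."""
    return ChainParameters.from_targets(240, 1.0, 5.0)


@pytest.fixture(scope="session")
def params_small():
    return ChainParameters.from_targets(16, 1.0, 2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def knot_fixtures():
    """Parametric rings for every supported knot type (moderate N for speed)."""
    labels = {
        "0_1": parametric_knot("0_1", N=61),
        "3_1": parametric_knot("3_1", N=121),
        "3_1L": parametric_knot("3_1", N=121, chirality="left"),
        "4_1": parametric_knot("4_1", N=161),
        "5_1": parametric_knot("5_1", N=161),
        "5_1L": parametric_knot("5_1", N=161, chirality="left"),
        "5_2": parametric_knot("5_2", N=161),
    }
    return labels
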