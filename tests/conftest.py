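import numpy as np
import pytest

from picarc import center_whiten
from picarc.reference import ReferenceParams
from picarc.simulate import SimulationSpec, five_compound_fixture, make_dataset


@pytest.fixture(scope="session")
def fixture5():
    """The five-compound benchmark mixture with its ground truth."""
    spec = five_compound_fixture()
    X, A, S = make_dataset(spec)
    return spec, X, A, S


@pytest.fixture(scope="session")
def whitened5(fixture5):
    _, X, _, _ = fixture5
    return center_whiten(X)


@pytest.fixture(scope="session")
def one_compound():
    spec = SimulationSpec(t=101, m=21, thetas=(ReferenceParams(30, 5),), seed=3)
    X, A, S = make_dataset(spec)
    return spec, X, A, S


@pytest.fixture(scope="session")
def two_compound():
    spec = SimulationSpec(
        t=101, m=31, thetas=(ReferenceParams(30, 5), ReferenceParams(60, 8)), seed=11
    )
    X, A, S = make_dataset(spec)
    return spec, X, A, S


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
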