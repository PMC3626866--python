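import numpy as np
import pytest

from strainopt.model import MetabolicModel
from strainopt.fixtures import make_branched_fixture, make_linear_fixture


@pytest.fixture
def tl3():
    """3-reaction chain with the planted middle bottleneck (SSU = (30, 5, 30),
    vmax(R2) = 5, kinetic capacity distributions on R2)."""
    return make_linear_fixture(3)


@pytest.fixture
def branched():
    """Two competing branches; the target branch has two serial bottlenecks."""
    return make_branched_fixture(2)


@pytest.fixture
def chain_model():
    """Plain irreversible chain R1 -> R2 -> R3 (uptake, conversion, export)."""
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["R1", "R2", "R3"],
        S=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        reversible=np.zeros(3, dtype=bool),
        target_id="R3",
    )
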