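import numpy as np
import pytest

from ngeni.fixtures import FixtureSpec, helix_chain, make_pair
from ngeni.structures import CoarseGrainedStructure


def bead_structure(coords, label="beads"):
    coords = np.asarray(coords, float)
    ids = [("A", str(i + 1), "GLY") for i in range(coords.shape[0])]
    return CoarseGrainedStructure(ids, coords, label=label)


@pytest.fixture
def hinge_pair():
    """Default hinge fixture: 20 beads, 60 degree bend (~2.4 A RMSD)."""
    return make_pair(FixtureSpec(kind="hinge", n=20))


@pytest.fixture
def helix20():
    return bead_structure(helix_chain(20), label="helix20")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
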