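import numpy as np
import pytest

from helixweaver.fixtures import make_toy_motif_library
from helixweaver.library import MotifLibrary


@pytest.fixture(scope="session")
def toy_library() -> MotifLibrary:
    """Six synthetic motifs (two per bend class)."""
    return make_toy_motif_library(2, seed=11)


@pytest.fixture(scope="session")
def full_library() -> MotifLibrary:
    """Eighteen synthetic motifs (six per bend class), loops 1-5 residues."""
    return make_toy_motif_library(6, seed=7)


@pytest.fixture(scope="session")
def single_motif_library(toy_library) -> MotifLibrary:
    return MotifLibrary(records=[toy_library.records[0]], provenance={})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()
    t = rng.normal(scale=20.0, size=3)
    return R, t
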