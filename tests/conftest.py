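import numpy as np
import pytest

from synfold import synthetic
from synfold.synthetic import HelixBuildSpec, PlannedPair


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def ideal_helix():
    """15-residue ideal alpha-helix along +z, noiseless."""
    return synthetic.build_helix(HelixBuildSpec(n_residues=15))


@pytest.fixture
def toy_complex():
    """Two 6-residue chains with 5 intermolecular contacts at 4.0 A."""
    plan = [PlannedPair(i, i, 4.0) for i in range(1, 6)]
    return synthetic.build_toy_complex(6, 6, plan)


def random_rotation(rng):
    """Uniform-ish random proper rotation matrix."""
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
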