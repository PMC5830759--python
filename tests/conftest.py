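import numpy as np
import pytest

from softpbd.forces import MaterialParams, ParticleSystem, Springs


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def fig8_material():
    """Parameter set of the nonlinearity figure (cubic-to-linear spring)."""
    return MaterialParams(k1=0.25, k2=10.0, b0=2.0, b1=1000.0, dl_c=1.0,
                          alpha=0.0)


@pytest.fixture
def two_node_system():
    """Two unit-mass nodes one rest-length apart along x."""
    x = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    return ParticleSystem.from_positions(x, np.ones(2))


def make_system(x, masses):
    return ParticleSystem.from_positions(np.asarray(x, float),
                                         np.asarray(masses, float))


def make_springs(pairs_rest):
    i, j, l0 = zip(*pairs_rest)
    return Springs(i, j, l0)
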