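import numpy as np
import pytest

from mesodpd import engine, fixtures


@pytest.fixture(scope="session")
def demo_set():
    return fixtures.demo_particle_set(range_x=20.0, T=298.0)


@pytest.fixture(scope="session")
def scheme_a():
    return fixtures.scheme_a()


@pytest.fixture(scope="session")
def scheme_b():
    return fixtures.scheme_b()


@pytest.fixture
def two_bead_state():
    """Two beads of one type at distance 0.5 in a periodic 5³ box."""

    def make(r=0.5, a=25.0, bonded=False, box=(5.0, 5.0, 5.0),
             boundary="periodic_xyz", vel=None):
        pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
        v = np.zeros((2, 3)) if vel is None else np.asarray(vel, float)
        bonds = np.array([[0, 1]]) if bonded else np.empty((0, 2), int)
        state = engine.BoxState(pos, v, np.zeros(2, int), np.zeros(2, int),
                                bonds, engine.BoxSpec(box, boundary),
                                type_names=["W"])
        pset = fixtures._UniformSet(a)
        return state, pset

    return make


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
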