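import numpy as np
import pytest

from crnreduce import fixtures as fx


@pytest.fixture
def example1():
    return fx.example1_network()


@pytest.fixture
def example1_driven():
    return fx.example1_driven()


@pytest.fixture
def two_state():
    return fx.two_state()


@pytest.fixture
def figure1_network():
    """The 4-complex mixed network: 2X1+X2 <-> X3, X3 <-> X1+2X2, 2X1+X2 -> X4
    (one consistent reading of the depicted edges), all mass action."""
    from crnreduce.fixtures import _rev_mass_action
    from crnreduce.kinetics import make_rate_law
    from crnreduce.network import Species, build_complexes

    f1, r1 = _rev_mass_action(1.0, 0.5)
    f2, r2 = _rev_mass_action(2.0, 1.0)
    irr = make_rate_law("mass_action", k=0.3)
    species = [Species(f"X{i}", x0=1.0) for i in range(1, 5)]
    return build_complexes(
        [({"X1": 2, "X2": 1}, {"X3": 1}, f1),
         ({"X3": 1}, {"X1": 2, "X2": 1}, r1),
         ({"X3": 1}, {"X1": 1, "X2": 2}, f2),
         ({"X1": 1, "X2": 2}, {"X3": 1}, r2),
         ({"X1": 2, "X2": 1}, {"X4": 1}, irr)],
        species=species,
        name="figure1",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
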