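import numpy as np
import pytest

from rpalattice.lattice import BoundRPA, LatticeState, Mode, RateSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def basic_rates():
    return RateSet("test", k_bind=1e-4, k_off20=1e-3, k_ext=5e-3, k_retr=2e-3)


def make_state(L, *placements):
    """placements: (start, 20|30) tuples, already disjoint."""
    mols = [
        BoundRPA(s, Mode.PBM20 if fp == 20 else Mode.FLBM30)
        for s, fp in sorted(placements)
    ]
    state = LatticeState(L, mols)
    state.validate()
    return state


@pytest.fixture
def state_factory():
    return make_state
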