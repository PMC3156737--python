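import numpy as np
import pytest

from fapscreen.chemgraph import parse_molecule
from fapscreen.encoder import encode_molecule
from fapscreen.ensemble import BoltzmannConfig
from fapscreen.fixtures import EnsembleSpec, simulate_ensemble
from fapscreen.gmmfit import EmConfig


@pytest.fixture
def benzene():
    return parse_molecule("c1ccccc1", name="benzene")


@pytest.fixture
def butane():
    return parse_molecule("CCCC", name="butane")


@pytest.fixture
def pentane():
    return parse_molecule("CCCCC", name="pentane")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fast_em():
    return EmConfig(max_iterations=100, restarts=2, seed=11)


@pytest.fixture(scope="session")
def encoded_hexane(fast_em):
    ens = simulate_ensemble(EnsembleSpec(template="chain:6", n_conformers=40, seed=2))
    return encode_molecule(ens, fast_em, BoltzmannConfig())
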