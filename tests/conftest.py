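import numpy as np
import pytest

from evokuramoto import (
    ConnectomeSpec,
    GameParams,
    complete_graph,
    derive_reproduction_graph,
    synth_connectome,
)


@pytest.fixture(scope="session")
def default_params() -> GameParams:
    """Standard operating point: B0=0.15, beta0=0.95*B0, c=0.1, delta=0.2,
    mu=1e-4, m=20, alpha=0.5."""
    return GameParams()


@pytest.fixture(scope="session")
def wellmixed20():
    gi = complete_graph(20)
    return gi, derive_reproduction_graph(gi)


@pytest.fixture(scope="session")
def connectome_like():
    """Census-exact synthetic connectome-like graph (seeded)."""
    gi = synth_connectome(ConnectomeSpec(), seed=7)
    return gi, derive_reproduction_graph(gi)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
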