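import numpy as np
import pytest

from hypercoop import (
    DynamicsConfig,
    Hypergraph,
    StrategyState,
    build_full_overlap,
    make_scheme,
)


@pytest.fixture(scope="session")
def full_overlap_300() -> Hypergraph:
    """Random-regular hypergraph at full overlap: N=300, k_pair=4, k_tri=2."""
    return build_full_overlap(300, 4, 2, seed=101)


@pytest.fixture(scope="session")
def triangle_toy() -> Hypergraph:
    """One triangle plus its three pairwise sides: the 3-node oracle system."""
    return Hypergraph(3, pair_edges={(0, 1), (0, 2), (1, 2)}, triangles={(0, 1, 2)})


@pytest.fixture
def default_scheme():
    return make_scheme(-0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def mixed_state(n: int, rng: np.random.Generator, rho: float = 0.5) -> StrategyState:
    pair = (rng.random(n) < rho).astype(np.int8)
    tri = (rng.random(n) < rho).astype(np.int8)
    return StrategyState("vector", pair=pair, tri=tri)


@pytest.fixture
def default_cfg() -> DynamicsConfig:
    return DynamicsConfig(w=1 / 6, pswitch=0.5)
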