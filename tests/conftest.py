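import networkx as nx
import numpy as np
import pytest

from netalign import Network
from netalign.benchmark import make_clique, make_cycle, make_path


@pytest.fixture(scope="session")
def triangle() -> Network:
    return Network("k3", "abc", [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture(scope="session")
def path3() -> Network:
    return Network("p3", "abc", [("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def c6() -> Network:
    return make_cycle(6)


@pytest.fixture(scope="session")
def c4() -> Network:
    return make_cycle(4)


@pytest.fixture(scope="session")
def k4() -> Network:
    return make_clique(4)


def random_network(n: int, p: float, seed: int, name: str = "rand") -> Network:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Network(name, (str(v) for v in g.nodes), ((str(a), str(b)) for a, b in g.edges))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
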