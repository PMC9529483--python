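import numpy as np
import pytest
from hypothesis import settings

from netplast import BinaryNetwork

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def net_from_edges(n: int, edges) -> BinaryNetwork:
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(a)


def complete_graph(n: int) -> BinaryNetwork:
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return BinaryNetwork(a)


def path_graph(n: int) -> BinaryNetwork:
    return net_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star_graph(n_leaves: int) -> BinaryNetwork:
    return net_from_edges(n_leaves + 1, [(0, i + 1) for i in range(n_leaves)])


def two_triangles() -> BinaryNetwork:
    return net_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])


def random_graph(rng: np.random.Generator, n: int, p: float) -> BinaryNetwork:
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return BinaryNetwork(a + a.T)


def erdos_renyi(rng, n, k_mean):
    return random_graph(rng, n, k_mean / (n - 1))


def watts_strogatz(rng: np.random.Generator, n: int, k: int, p: float) -> BinaryNetwork:
    """Ring lattice of even degree k with probability-p rewired endpoints."""
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1
    iu, ju = np.nonzero(np.triu(a, 1))
    for i, j in zip(iu, ju):
        if rng.random() < p:
            choices = np.flatnonzero((a[i] == 0) & (np.arange(n) != i))
            if choices.size:
                new = rng.choice(choices)
                a[i, j] = a[j, i] = 0
                a[i, new] = a[new, i] = 1
    return BinaryNetwork(a)


@pytest.fixture(scope="session")
def canonical_study():
    """The canonical ADHD-like contrast study, run once for the session."""
    from netplast import adhd_like_spec, run_study
    return run_study(adhd_like_spec(seed=0))


@pytest.fixture(scope="session")
def small_graph_zoo():
    """200 seeded random graphs with n <= 8 spanning all densities."""
    rng = np.random.default_rng(20240901)
    zoo = []
    for _ in range(200):
        n = int(rng.integers(2, 9))
        p = float(rng.random())
        zoo.append(random_graph(rng, n, p))
    return zoo
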