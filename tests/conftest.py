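import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from richabund import RegionScenario, load_table1_fixture, simulate_region


# ---------------------------------------------------------------------------
# independent brute-force d-separation oracle (path-blocking enumeration)


def _descendants(g: nx.DiGraph, node):
    return nx.descendants(g, node) | {node}


def _path_blocked(g: nx.DiGraph, path, z: set) -> bool:
    """Is this undirected path blocked given conditioning set z?"""
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        into_prev = g.has_edge(prev, node)
        into_next = g.has_edge(nxt, node)
        if into_prev and into_next:  # collider
            if not (_descendants(g, node) & z):
                return True
        else:  # chain or fork
            if node in z:
                return True
    return False


def d_separated_bruteforce(g: nx.DiGraph, x: str, y: str, z: set) -> bool:
    """Enumerate every undirected simple path between x and y and check that
    all are blocked by z under the d-separation rules."""
    und = g.to_undirected()
    for path in nx.all_simple_paths(und, x, y):
        if not _path_blocked(g, path, set(z)):
            return False
    return True


def random_dag(rng: np.random.Generator, max_nodes: int = 6) -> nx.DiGraph:
    """A random DAG: random topological order, each forward edge kept with
    probability drawn per graph."""
    n = int(rng.integers(3, max_nodes + 1))
    names = [f"v{i}" for i in range(n)]
    order = list(rng.permutation(names))
    p = rng.uniform(0.15, 0.6)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(order[i], order[j])
    return g


# ---------------------------------------------------------------------------
# shared fixtures


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def msh_region():
    """One seeded synthetic region generated under the MSH regime."""
    return simulate_region(RegionScenario(regime="MSH", n_plots=500, seed=11))


@pytest.fixture(scope="session")
def msh_frame(msh_region) -> pd.DataFrame:
    return msh_region.to_frame()
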