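"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from gmlpath import PathDAG, PathEdge, PathNode, SimulationConfig, simulate_study
from gmlpath.pipeline import prepare_path_tables, standardize_path_tables
from gmlpath.simulate import sparrow_dag

# ---------------------------------------------------------------------------
# brute-force d-separation oracle (independent of networkx)
# ---------------------------------------------------------------------------


def _descendants(edges, node):
    out = set()
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for a, b in edges:
            if a == cur and b not in out:
                out.add(b)
                frontier.append(b)
    return out


def brute_force_d_separated(nodes, edges, x, y, z):
    """Enumerate every undirected simple path x..y; apply the blocking rules.

    A path is blocked if some non-collider on it is in z, or some collider
    on it has neither itself nor any descendant in z.  x and y are
    d-separated given z iff every path is blocked.
    """
    z = set(z)
    neighbors = {n: set() for n in nodes}
    for a, b in edges:
        neighbors[a].add(b)
        neighbors[b].add(a)

    def path_blocked(path):
        for i in range(1, len(path) - 1):
            prev, mid, nxt = path[i - 1], path[i], path[i + 1]
            into_mid_left = (prev, mid) in edges
            into_mid_right = (nxt, mid) in edges
            collider = into_mid_left and into_mid_right
            if collider:
                if mid not in z and not (_descendants(edges, mid) & z):
                    return True
            else:
                if mid in z:
                    return True
        return False

    stack = [[x]]
    while stack:
        path = stack.pop()
        cur = path[-1]
        if cur == y:
            if len(path) >= 2 and not path_blocked(path):
                return False
            continue
        for nxt in sorted(neighbors[cur]):
            if nxt not in path:
                stack.append(path + [nxt])
    return True


def random_dag(rng, n_nodes, edge_prob=0.4):
    names = [f"v{i}" for i in range(n_nodes)]
    edges = []
    for i, j in combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            edges.append((names[i], names[j]))
    dag = PathDAG(
        [PathNode(n) for n in names],
        [PathEdge(a, b) for a, b in edges],
    )
    return dag, set(names), set(edges)


@pytest.fixture(scope="session")
def oracle():
    return brute_force_d_separated


# ---------------------------------------------------------------------------
# study fixtures (shared across modules to amortize simulation cost)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(default_config):
    return simulate_study(default_config)


@pytest.fixture(scope="session")
def sparrow(default_config):
    return sparrow_dag(default_config)


@pytest.fixture(scope="session")
def std_tables(study, sparrow):
    tables = prepare_path_tables(study.nestlings, study.captures)
    std, _ = standardize_path_tables(sparrow, tables)
    return std


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
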