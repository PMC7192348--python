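import itertools

import networkx as nx
import numpy as np
import pytest

from comgrow import load_karate


@pytest.fixture(scope="session")
def karate():
    return load_karate()


@pytest.fixture
def two_triangles():
    """Two disjoint triangles."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


@pytest.fixture
def two_cliques_bridge():
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.compose(nx.complete_graph(4), nx.relabel_nodes(nx.complete_graph(4), {i: i + 4 for i in range(4)}))
    g.add_edge(0, 4)
    return g


def all_partitions(nodes):
    """Every set partition of an iterable (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for sub in all_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [sub[i] | {first}] + sub[i + 1:]
        yield sub + [{first}]


def nc_distribution(k, n_target, beta):
    """Exact distribution of the final community count by exhaustive
    enumeration of all growth trajectories (independent oracle: only uses
    the size-factor rule, never the package's sampler)."""
    dist = {}

    def rec(sizes, prob):
        n = sum(sizes)
        if n == n_target:
            dist[len(sizes)] = dist.get(len(sizes), 0.0) + prob
            return
        denom = n + beta
        for i, ni in enumerate(sizes):
            rec(sizes[:i] + (ni + 1,) + sizes[i + 1:], prob * ni / denom)
        if beta > 0:
            rec(sizes + (1,), prob * beta / denom)

    rec(tuple([1] * k), 1.0)
    return dist


def exact_auc(graph, test_edges, index):
    """Brute-force AUC over every (test edge, non-edge) pair."""
    from comgrow.linkpred import similarity

    train = graph.copy()
    train.remove_edges_from(test_edges)
    non_edges = [
        (u, v)
        for u, v in itertools.combinations(graph.nodes(), 2)
        if not graph.has_edge(u, v)
    ]
    wins = ties = 0
    for e in test_edges:
        s_e = similarity(index, train, *e)
        for ne in non_edges:
            s_n = similarity(index, train, *ne)
            if s_e > s_n:
                wins += 1
            elif s_e == s_n:
                ties += 1
    total = len(test_edges) * len(non_edges)
    return (wins + 0.5 * ties) / total
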