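"""Community statistics: modularity, Girvan–Newman detection, degree and
size extremes, and within-community tree depth.

Model-grown networks are scored on their own birth labels (the generative
partition); Girvan–Newman detection is meant for real networks that carry
no labels, such as the karate club graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import NotATreeError, UndefinedMeasureError

__all__ = [
    "NetworkReport",
    "modularity",
    "girvan_newman",
    "degree_stats",
    "community_stats",
    "max_tree_depth",
    "partition_from_labels",
    "labels_from_partition",
]

Community = Sequence[int] | set[int] | frozenset[int]


@dataclass
class NetworkReport:
    """One row of the model's summary tables.

    ``l_max`` is only defined in the tree-like regime; ``pr`` only when
    predictability was evaluated.
    """

    n_c: int
    s_max: int
    s_min: int
    d_max: int
    d_min: int
    q: float
    l_max: Optional[int] = None
    pr: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "N_c": self.n_c,
            "S_max": self.s_max,
            "S_min": self.s_min,
            "D_max": self.d_max,
            "D_min": self.d_min,
            "L_max": self.l_max,
            "Q": self.q,
            "Pr": self.pr,
        }


def partition_from_labels(labels: dict[int, int]) -> list[set[int]]:
    """Group a node -> community-label map into birth-ordered node sets."""
    out: dict[int, set[int]] = {}
    for node, lab in labels.items():
        out.setdefault(lab, set()).add(node)
    return [out[lab] for lab in sorted(out)]


def labels_from_partition(partition: Iterable[Community]) -> dict[int, int]:
    """Inverse of :func:`partition_from_labels`; labels are 1-based."""
    return {v: i + 1 for i, comm in enumerate(partition) for v in comm}


def modularity(graph: nx.Graph, partition: Iterable[Community]) -> float:
    """Newman–Girvan modularity Q = sum_i (e_ii - a_i^2), unweighted.

    ``e_ii`` is the fraction of edges inside community ``i`` and ``a_i``
    the fraction of edge ends attached to it.  Q = 0 for the one-community
    partition; Q is bounded by [-1/2, 1].
    """
    if graph.number_of_edges() == 0:
        raise UndefinedMeasureError("modularity is undefined for an edgeless graph")
    return float(
        nx.algorithms.community.modularity(graph, [set(c) for c in partition], weight=None)
    )


def _most_central_edge(graph: nx.Graph) -> tuple:
    """Highest-betweenness edge; ties broken by smallest sorted node pair."""
    bw = nx.edge_betweenness_centrality(graph)
    top = max(bw.values())
    candidates = [tuple(sorted(e)) for e, v in bw.items() if v >= top * (1 - 1e-9)]
    return min(candidates)


def girvan_newman(graph: nx.Graph) -> list[set[int]]:
    """Girvan–Newman partition of maximum modularity.

    Repeatedly removes the edge of highest betweenness (recomputed after
    every removal) and returns, over the whole removal sequence including
    the starting connected components, the partition with the largest Q;
    among equal-Q cuts the one with fewest communities wins.  An edgeless
    graph yields singleton communities.
    """
    if graph.number_of_edges() == 0:
        return [{v} for v in graph.nodes()]
    candidates = [tuple(nx.connected_components(graph))]
    candidates.extend(
        nx.algorithms.community.girvan_newman(graph, most_valuable_edge=_most_central_edge)
    )
    best, best_q = None, -float("inf")
    for part in candidates:  # yielded in increasing community count
        q = modularity(graph, part)
        if q > best_q + 1e-12:
            best, best_q = part, q
    return [set(c) for c in best]


def degree_stats(graph: nx.Graph) -> tuple[int, int]:
    """(D_max, D_min) over all nodes."""
    degrees = [d for _, d in graph.degree()]
    if not degrees:
        raise UndefinedMeasureError("degree stats of an empty graph are undefined")
    return max(degrees), min(degrees)


def community_stats(partition: Iterable[Community]) -> tuple[int, int, int]:
    """(N_c, S_max, S_min) of a partition."""
    sizes = [len(c) for c in partition]
    if not sizes:
        raise UndefinedMeasureError("community stats of an empty partition are undefined")
    return len(sizes), max(sizes), min(sizes)


def max_tree_depth(
    graph: nx.Graph,
    partition: Sequence[Community],
    roots: Sequence[int],
) -> int:
    """Maximum root depth over the communities' internal trees.

    Each community's induced subgraph must be a tree (the tree-like
    regime guarantees this: every member after the first attaches to
    exactly one earlier member).  The depth of a community is the
    eccentricity of its root — its oldest member for model networks —
    inside the induced subgraph; a singleton community has depth 0.
    """
    if len(partition) != len(roots):
        raise ValueError("one root per community is required")
    deepest = 0
    for comm, root in zip(partition, roots):
        sub = graph.subgraph(comm)
        if root not in sub:
            raise ValueError(f"root {root!r} is not a member of its community")
        if not nx.is_tree(sub):
            raise NotATreeError(
                "community induced subgraph is not a tree "
                f"(n={sub.number_of_nodes()}, edges={sub.number_of_edges()})"
            )
        depth = max(nx.single_source_shortest_path_length(sub, root).values())
        deepest = max(deepest, depth)
    return deepest
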