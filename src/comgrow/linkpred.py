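"""Similarity-index link prediction, sampled AUC, and the community
predictability statistic S_pr.

S_pr compares how well a similarity index recovers held-out links inside
each community against how well it recovers held-out links overall:

    S_pr = (1/N) * sum_i (S_in_i - S_all_i) / S_all_i

over the N communities large enough to hold out a link, where both
accuracies are link-prediction AUCs under an identical split protocol.
S_pr > 0.1 is read as a very predictable community structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import InvalidParameterError, UndefinedMeasureError

__all__ = [
    "INDICES",
    "EvalConfig",
    "PredictabilityResult",
    "similarity",
    "auc",
    "predictability",
]

INDICES = ("CN", "LHN1", "HDI", "HEI")

# A scorer maps (adjacency bool matrix, degree vector, u idx array, v idx
# array) to a score array; custom callables may be passed wherever an
# index name is accepted.
Scorer = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _cn(adj, deg, us, vs):
    return (adj[us] & adj[vs]).sum(axis=1).astype(float)


def _lhn1(adj, deg, us, vs):
    cn = _cn(adj, deg, us, vs)
    denom = deg[us] * deg[vs]
    return np.divide(cn, denom, out=np.zeros_like(cn), where=denom > 0)


def _hdi(adj, deg, us, vs):
    cn = _cn(adj, deg, us, vs)
    denom = np.maximum(deg[us], deg[vs]).astype(float)
    return np.divide(cn, denom, out=np.zeros_like(cn), where=denom > 0)


def _hei(adj, deg, us, vs):
    # hub-enhanced score for tree-like networks: the larger endpoint
    # degree; hubs (branch roots) attract the missing links
    return np.maximum(deg[us], deg[vs]).astype(float)


_SCORERS: dict[str, Scorer] = {"CN": _cn, "LHN1": _lhn1, "HDI": _hdi, "HEI": _hei}


def _resolve_scorer(index: str | Scorer) -> Scorer:
    if callable(index):
        return index
    try:
        return _SCORERS[index]
    except KeyError:
        raise InvalidParameterError(
            f"unknown index {index!r}; expected one of {INDICES} or a callable"
        ) from None


@dataclass(frozen=True)
class EvalConfig:
    """Split-and-score protocol knobs for AUC and predictability."""

    test_fraction: float = 0.1
    n_reps: int = 20
    n_auc_samples: int = 10_000
    index: str | Scorer = "CN"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise InvalidParameterError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction!r}"
            )
        if self.n_reps < 1 or self.n_auc_samples < 1:
            raise InvalidParameterError("n_reps and n_auc_samples must be >= 1")


@dataclass
class PredictabilityResult:
    """Per-community and aggregate predictability."""

    s_in: dict[int, float]
    s_all: float
    s_pr: float
    n_communities_evaluated: int
    skipped: list[int] = field(default_factory=list)


def similarity(index: str | Scorer, graph: nx.Graph, x, y) -> float:
    """Similarity score of one node pair on the given graph.

    CN = |G(x) n G(y)|; LHN1 = CN / (k_x k_y); HDI = CN / max(k_x, k_y);
    HEI = max(k_x, k_y).  Degree-zero denominators score 0.
    """
    if x == y:
        raise InvalidParameterError("similarity of a node with itself is undefined")
    nodes = list(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_numpy_array(graph, nodelist=nodes, dtype=bool, weight=None)
    deg = adj.sum(axis=1).astype(float)
    scorer = _resolve_scorer(index)
    return float(
        scorer(adj, deg, np.array([idx[x]]), np.array([idx[y]]))[0]
    )


def _sample_nonedges(
    adj_full: np.ndarray, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform node pairs that are non-edges of the full graph."""
    n = adj_full.shape[0]
    if not (~adj_full).sum() > n:  # only the diagonal is free
        raise UndefinedMeasureError("graph is complete; no non-edge to sample")
    us = np.empty(0, dtype=np.intp)
    vs = np.empty(0, dtype=np.intp)
    while us.size < n_samples:
        need = n_samples - us.size
        a = rng.integers(0, n, size=2 * need + 8)
        b = rng.integers(0, n, size=2 * need + 8)
        ok = (a != b) & ~adj_full[a, b]
        us = np.concatenate([us, a[ok]])
        vs = np.concatenate([vs, b[ok]])
    return us[:n_samples], vs[:n_samples]


def auc(
    graph: nx.Graph,
    test_edges: Sequence[tuple],
    index: str | Scorer,
    cfg: EvalConfig,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Sampled link-prediction AUC.

    ``graph`` is the full network; ``test_edges`` are removed to form the
    training graph on which scores are computed.  ``cfg.n_auc_samples``
    comparisons are drawn, each pitting a uniformly chosen test edge
    against a uniformly chosen non-edge of the full graph; AUC counts
    wins plus half-ties.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if not test_edges:
        raise UndefinedMeasureError("AUC needs at least one test edge")
    nodes = list(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    adj_full = nx.to_numpy_array(graph, nodelist=nodes, dtype=bool, weight=None)
    adj_train = adj_full.copy()
    te = np.array([[idx[u], idx[v]] for u, v in test_edges], dtype=np.intp)
    adj_train[te[:, 0], te[:, 1]] = False
    adj_train[te[:, 1], te[:, 0]] = False
    deg_train = adj_train.sum(axis=1).astype(float)
    scorer = _resolve_scorer(index)

    pick = rng.integers(0, len(te), size=cfg.n_auc_samples)
    s_edge = scorer(adj_train, deg_train, te[pick, 0], te[pick, 1])
    nu, nv = _sample_nonedges(adj_full, cfg.n_auc_samples, rng)
    s_non = scorer(adj_train, deg_train, nu, nv)
    return float((np.count_nonzero(s_edge > s_non) + 0.5 * np.count_nonzero(s_edge == s_non)) / cfg.n_auc_samples)


def _n_holdout(n_links: int, fraction: float) -> int:
    return max(1, int(round(n_links * fraction)))


def predictability(
    graph: nx.Graph,
    partition: Sequence[Iterable],
    cfg: EvalConfig,
) -> PredictabilityResult:
    """Community predictability S_pr under a paired split protocol.

    For each repetition, a ``test_fraction`` sample of every evaluable
    community's internal links is held out and scored (S_in_i), and a
    ``test_fraction`` sample of all links is held out and scored with the
    same machinery (S_all).  Communities whose internal link count is
    below ``ceil(1 / test_fraction)`` are skipped and reported.  Averages
    are over ``n_reps`` repetitions; the aggregate is the community mean
    of the relative excess (S_in_i - S_all) / S_all.
    """
    rng = np.random.default_rng(cfg.seed)
    communities = [set(c) for c in partition]
    internal: dict[int, list[tuple]] = {}
    skipped: list[int] = []
    threshold = math.ceil(1.0 / cfg.test_fraction)
    for i, comm in enumerate(communities, start=1):
        edges = [e for e in graph.subgraph(comm).edges()]
        if len(edges) >= threshold:
            internal[i] = edges
        else:
            skipped.append(i)
    if not internal:
        raise UndefinedMeasureError(
            "no community has enough internal links to evaluate"
        )
    all_edges = list(graph.edges())
    s_in_acc = {i: 0.0 for i in internal}
    s_all_acc = 0.0
    for _ in range(cfg.n_reps):
        k_all = _n_holdout(len(all_edges), cfg.test_fraction)
        test_all = [all_edges[j] for j in rng.choice(len(all_edges), size=k_all, replace=False)]
        s_all_acc += auc(graph, test_all, cfg.index, cfg, rng)
        for i, edges in internal.items():
            k_in = _n_holdout(len(edges), cfg.test_fraction)
            test_in = [edges[j] for j in rng.choice(len(edges), size=k_in, replace=False)]
            s_in_acc[i] += auc(graph, test_in, cfg.index, cfg, rng)
    s_all = s_all_acc / cfg.n_reps
    s_in = {i: v / cfg.n_reps for i, v in s_in_acc.items()}
    s_pr = float(np.mean([(v - s_all) / s_all for v in s_in.values()]))
    return PredictabilityResult(
        s_in=s_in,
        s_all=s_all,
        s_pr=s_pr,
        n_communities_evaluated=len(s_in),
        skipped=skipped,
    )
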