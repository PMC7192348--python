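"""Distributive-link growth model for networks with evolving communities.

The process starts from a fully connected seed of ``k`` nodes, each its own
community.  At every step one new node arrives and either founds a new
community or joins an existing one; the choice is drawn from a single
probability mass function over the ``c`` existing communities plus a NEW
option whose weight is governed by the free control parameter ``beta``:

    P(join community i) = n_i / (n + beta),      i = 1..c
    P(found community c+1) = beta / (n + beta),

where ``n_i`` is the size of community ``i`` and ``n = sum_i n_i`` the
current node count.  These factors sum identically to one (a Chinese-
restaurant-style rule) and reproduce both limits of the model: ``beta = 0``
freezes the community count at ``k`` and ``beta -> inf`` makes every step
open a fresh community, so the final count tends to ``n``.  The product of
all the factors, recorded per step as ``p_inverse``, is the quantity whose
inverse controls the appearance of new communities in the model's original
formulation.

The new node then attaches ``m`` links.  A community founder links to
``m`` uniformly chosen existing nodes (necessarily in other communities).
A node joining community ``l`` draws each of its ``m`` partners
independently: with probability ``p`` from inside ``l`` (uniform over the
current members, or biased to the community's oldest member in the
``oldest_biased`` variant), with probability ``1 - p`` uniformly from the
rest of the network.  Partners are drawn without replacement; when the
preferred pool runs out of unused partners the remaining links fall back
to the other pool, internal pool first.

With ``m = 1`` and ``p = 1`` the model grows a tree in which communities
are branches; with ``m = k > 1`` it grows clustered "regular" networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "ModelParams",
    "GrowthState",
    "CommunityPMF",
    "init_seed",
    "resolve_beta",
    "community_pmf",
    "add_node",
    "grow",
    "BETA_POLICIES",
]

#: dynamic policies re-resolve beta each step from the pre-step community sizes
BETA_POLICIES = ("fixed", "min_size", "mean_size", "max_size")
WITHIN_CHOICES = ("uniform", "oldest_biased")
COMMUNITY_CHOICES = ("size", "age")


@dataclass(frozen=True)
class ModelParams:
    """Full parameterisation of one growth run.

    Parameters
    ----------
    k
        Seed size: the initial fully connected network has ``k`` nodes,
        each a singleton community.  ``k >= 1``.
    m
        Links attached per new node, ``1 <= m <= k``.
    p
        Probability that each of a joining node's links is internal to its
        community (applied independently per link).
    n_target
        Final node count; the model runs ``n_target - k`` growth steps.
    beta_policy
        ``"fixed"`` (use ``beta_value``) or one of ``"min_size"``,
        ``"mean_size"``, ``"max_size"``, which re-evaluate beta every step
        on the current community sizes.
    beta_value
        The constant beta (``>= 0``) when ``beta_policy == "fixed"``.
    within_choice
        ``"uniform"``: internal partners are uniform over the community's
        current members.  ``"oldest_biased"``: with probability
        ``oldest_q`` the partner is the community's oldest (first) member,
        otherwise uniform — emulates haplotype networks whose per-group
        root is the hub.
    oldest_q
        Bias strength for ``oldest_biased`` (default 0.9).
    community_choice
        ``"size"`` (default): the self-normalising size-proportional rule
        above.  ``"age"``: an alternative age-increasing weighting in
        which the weight of community ``i`` is the inverse of the partial
        product of size factors up to ``i`` (later-born communities are
        favoured more aggressively); kept as a configurable variant.
    seed
        RNG seed for :func:`grow`; ``None`` draws fresh entropy.
    """

    k: int
    m: int
    p: float
    n_target: int
    beta_policy: str = "min_size"
    beta_value: Optional[float] = None
    within_choice: str = "uniform"
    oldest_q: float = 0.9
    community_choice: str = "size"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise InvalidParameterError(f"k must be an integer >= 1, got {self.k!r}")
        if not (isinstance(self.m, (int, np.integer)) and 1 <= self.m <= self.k):
            raise InvalidParameterError(
                f"m must satisfy 1 <= m <= k={self.k}, got {self.m!r}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError(f"p must lie in [0, 1], got {self.p!r}")
        if self.n_target < self.k:
            raise InvalidParameterError(
                f"n_target must be >= k={self.k}, got {self.n_target!r}"
            )
        if self.beta_policy not in BETA_POLICIES:
            raise InvalidParameterError(
                f"beta_policy must be one of {BETA_POLICIES}, got {self.beta_policy!r}"
            )
        if self.beta_policy == "fixed":
            if self.beta_value is None or self.beta_value < 0:
                raise InvalidParameterError(
                    "fixed beta policy requires beta_value >= 0, got "
                    f"{self.beta_value!r}"
                )
        if self.within_choice not in WITHIN_CHOICES:
            raise InvalidParameterError(
                f"within_choice must be one of {WITHIN_CHOICES}, got "
                f"{self.within_choice!r}"
            )
        if not 0.0 <= self.oldest_q <= 1.0:
            raise InvalidParameterError(f"oldest_q must lie in [0, 1], got {self.oldest_q!r}")
        if self.community_choice not in COMMUNITY_CHOICES:
            raise InvalidParameterError(
                f"community_choice must be one of {COMMUNITY_CHOICES}, got "
                f"{self.community_choice!r}"
            )

    def with_seed(self, seed: Optional[int]) -> "ModelParams":
        return replace(self, seed=seed)


@dataclass
class GrowthState:
    """The evolving labelled graph.

    ``communities`` is birth-ordered: entry ``i`` (0-based) is the member
    list of the community labelled ``i + 1``, members in joining order, so
    ``communities[i][0]`` is that community's oldest node.  Node ids are
    0-based in birth order.
    """

    graph: nx.Graph
    communities: list[list[int]]
    node_birth: dict[int, int]
    node_community: dict[int, int]
    #: per-step log of (resolved beta, p_inverse); appended by add_node
    step_log: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def community_sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.communities], dtype=float)

    def partition(self) -> list[set[int]]:
        """The generative partition as a list of node sets in birth order."""
        return [set(c) for c in self.communities]

    def check_invariants(self) -> None:
        sizes = self.community_sizes()
        assert int(sizes.sum()) == self.n
        assert not any(u == v for u, v in self.graph.edges())
        assert set(self.node_community) == set(self.graph.nodes())


@dataclass(frozen=True)
class CommunityPMF:
    """Per-step distribution over {existing communities 1..c, NEW}.

    ``probs[i]`` (0-based ``i < c``) is the probability of joining
    community ``i + 1``; ``probs[c]`` is the probability of founding a new
    one.  ``p_inverse`` is the literal product of all ``c + 1`` factors,
    logged for diagnostics.
    """

    probs: np.ndarray
    beta_used: float
    p_inverse: float

    @property
    def p_new(self) -> float:
        return float(self.probs[-1])


def init_seed(k: int) -> GrowthState:
    """Fully connected seed of ``k`` nodes, each a singleton community."""
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise InvalidParameterError(f"k must be an integer >= 1, got {k!r}")
    graph = nx.complete_graph(int(k))
    return GrowthState(
        graph=graph,
        communities=[[i] for i in range(k)],
        node_birth={i: i for i in range(k)},
        node_community={i: i + 1 for i in range(k)},
    )


def resolve_beta(
    policy: str, state: GrowthState, value: Optional[float] = None
) -> float:
    """Resolve beta for the coming step from the pre-step community sizes."""
    if policy == "fixed":
        if value is None or value < 0:
            raise InvalidParameterError(f"fixed beta requires value >= 0, got {value!r}")
        return float(value)
    sizes = state.community_sizes()
    if policy == "min_size":
        return float(sizes.min())
    if policy == "mean_size":
        return float(sizes.mean())
    if policy == "max_size":
        return float(sizes.max())
    raise InvalidParameterError(f"unknown beta policy {policy!r}")


def community_pmf(
    state: GrowthState, beta: float, community_choice: str = "size"
) -> CommunityPMF:
    """Distribution over the join/found options for the next node.

    The default ``size`` rule uses the factors ``n_i / (n + beta)`` and
    ``beta / (n + beta)`` directly; they are exactly normalised.  The
    ``age`` variant weights community ``i`` by the inverse of the partial
    product ``prod_{j<=i} n_j / (n + beta)`` (so later-born communities
    carry geometrically larger weight) and the NEW option by one further
    factor ``(n + beta) / beta``; weights are computed in log space and
    normalised.  Either way ``beta = 0`` pins the NEW probability to zero.
    """
    if beta < 0:
        raise InvalidParameterError(f"beta must be >= 0, got {beta!r}")
    sizes = state.community_sizes()
    n = float(sizes.sum())
    denom = n + beta
    factors = sizes / denom
    # literal product of all c+1 factors; may underflow to 0 for large c,
    # which is fine for a diagnostic
    p_inverse = float(np.prod(factors) * (beta / denom))

    if community_choice == "size":
        probs = np.append(factors, beta / denom)
    elif community_choice == "age":
        log_w = -np.cumsum(np.log(factors))  # inverse partial products
        if beta > 0:
            log_w = np.append(log_w, log_w[-1] + math.log(denom / beta))
            log_w -= log_w.max()
            probs = np.exp(log_w)
        else:
            probs = np.append(np.exp(log_w - log_w.max()), 0.0)
        probs = probs / probs.sum()
    else:
        raise InvalidParameterError(f"unknown community_choice {community_choice!r}")
    return CommunityPMF(probs=probs, beta_used=float(beta), p_inverse=p_inverse)


def _categorical(rng: np.random.Generator, probs: np.ndarray) -> int:
    """One draw from a categorical distribution (single uniform variate)."""
    cdf = np.cumsum(probs)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right").clip(0, len(probs) - 1))


def add_node(state: GrowthState, params: ModelParams, rng: np.random.Generator) -> GrowthState:
    """Execute one growth step in place and return the state.

    Draw order (fixed for reproducibility): community/NEW choice from the
    step PMF, then per link — internal/external Bernoulli(p), oldest-bias
    Bernoulli(q) where applicable, partner choice within the pool.
    """
    n_before = state.n
    beta = resolve_beta(params.beta_policy, state, params.beta_value)
    pmf = community_pmf(state, beta, params.community_choice)
    state.step_log.append((pmf.beta_used, pmf.p_inverse))

    c = state.n_communities
    choice = _categorical(rng, pmf.probs)
    new = n_before  # node ids are birth-ordered
    n_links = min(params.m, n_before)

    if choice == c:  # found community c + 1
        # the founder's links go to uniformly chosen existing nodes, which
        # all belong to other communities by construction
        targets = rng.choice(n_before, size=n_links, replace=False).tolist()
        state.communities.append([new])
        label = c + 1
    else:
        label = choice + 1
        members = state.communities[choice]
        member_set = set(members)
        internal = [v for v in members]  # joining order == birth order
        external = [v for v in range(n_before) if v not in member_set]
        used: set[int] = set()
        targets = []
        for _ in range(n_links):
            want_internal = rng.random() < params.p
            pool_internal = [v for v in internal if v not in used]
            pool_external = [v for v in external if v not in used]
            if want_internal:
                pool = pool_internal if pool_internal else pool_external
                use_oldest = (
                    params.within_choice == "oldest_biased"
                    and pool is pool_internal
                    and rng.random() < params.oldest_q
                )
                if use_oldest:
                    partner = pool_internal[0]  # community's oldest member
                else:
                    partner = pool[int(rng.integers(len(pool)))]
            else:
                pool = pool_external if pool_external else pool_internal
                partner = pool[int(rng.integers(len(pool)))]
            used.add(partner)
            targets.append(partner)
        state.communities[choice].append(new)

    state.graph.add_node(new)
    state.graph.add_edges_from((new, t) for t in targets)
    state.node_birth[new] = n_before
    state.node_community[new] = label
    return state


def grow(params: ModelParams, rng: Optional[np.random.Generator] = None) -> GrowthState:
    """Run the full growth process: seed plus ``n_target - k`` steps."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_seed(params.k)
    for _ in range(params.n_target - params.k):
        add_node(state, params, rng)
    return state
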