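"""Named model configurations mirroring the documented experiments, plus
the report machinery that turns a grown network into one summary-table row.

Presets
-------
``regular_min`` / ``regular_mean`` / ``regular_max``
    Regular networks: k=3, m=3, p=0.97, n=50 with beta tied to the
    min / mean / max community size.
``tree_basic``
    Tree-like network: k=3, m=1, p=1, n=50, beta = min community size.
``sars_like``
    Emulates a coronavirus haplotype evolutionary network (59 nodes,
    59 links, 5 groups whose root haplotype is the group hub): k=3, m=1,
    p=1, n=59, beta = min community size, and within-community attachment
    biased to the community's oldest node with probability 0.9.
``karate_like``
    Regular network sized like the karate club: k=3, m=2, p=0.9, n=34,
    beta = min community size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NotATreeError, UndefinedMeasureError
from .growth import GrowthState, ModelParams, grow
from .linkpred import EvalConfig, predictability
from .metrics import (
    NetworkReport,
    community_stats,
    degree_stats,
    max_tree_depth,
    modularity,
)

__all__ = ["Preset", "PRESETS", "get_preset", "network_report", "run_preset", "baseline_ba"]


@dataclass(frozen=True)
class Preset:
    name: str
    params: ModelParams
    index: str  # similarity index used for the Pr column
    tree_like: bool = False
    #: table row the preset mirrors (documentation, not an assertion)
    expected: dict = field(default_factory=dict)


PRESETS: dict[str, Preset] = {
    "regular_min": Preset(
        "regular_min",
        ModelParams(k=3, m=3, p=0.97, n_target=50, beta_policy="min_size"),
        index="CN",
        expected={"N_c": 5, "S_max": 20, "D_max": 17, "D_min": 3},
    ),
    "regular_mean": Preset(
        "regular_mean",
        ModelParams(k=3, m=3, p=0.97, n_target=50, beta_policy="mean_size"),
        index="CN",
        expected={"N_c": 8, "S_max": 17, "D_max": 14, "D_min": 3},
    ),
    "regular_max": Preset(
        "regular_max",
        ModelParams(k=3, m=3, p=0.97, n_target=50, beta_policy="max_size"),
        index="CN",
        expected={"N_c": 17, "S_max": 14, "D_max": 13, "D_min": 3},
    ),
    "tree_basic": Preset(
        "tree_basic",
        ModelParams(k=3, m=1, p=1.0, n_target=50, beta_policy="min_size"),
        index="HEI",
        tree_like=True,
    ),
    "sars_like": Preset(
        "sars_like",
        ModelParams(
            k=3,
            m=1,
            p=1.0,
            n_target=59,
            beta_policy="min_size",
            within_choice="oldest_biased",
            oldest_q=0.9,
        ),
        index="HEI",
        tree_like=True,
        expected={
            "N_c": 5, "L_max": 2, "S_max": 34, "D_max": 31, "D_min": 1,
            "Q": 0.5208, "Pr": 0.0071,
        },
    ),
    "karate_like": Preset(
        "karate_like",
        ModelParams(k=3, m=2, p=0.9, n_target=34, beta_policy="min_size"),
        index="CN",
        expected={
            "N_c": 5, "S_max": 12, "S_min": 1, "D_max": 11, "D_min": 2,
            "Q": 0.4746, "Pr": 0.0554,
        },
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def network_report(
    state: GrowthState,
    index: str = "CN",
    tree_like: bool = False,
    eval_cfg: Optional[EvalConfig] = None,
    with_pr: bool = True,
) -> NetworkReport:
    """Score a grown network on its own birth labels."""
    partition = state.partition()
    n_c, s_max, s_min = community_stats(partition)
    d_max, d_min = degree_stats(state.graph)
    q = modularity(state.graph, partition)
    l_max = None
    if tree_like:
        roots = [members[0] for members in state.communities]
        try:
            l_max = max_tree_depth(state.graph, state.partition(), roots)
        except NotATreeError:
            l_max = None
    pr = None
    if with_pr:
        cfg = eval_cfg if eval_cfg is not None else EvalConfig(index=index)
        try:
            pr = predictability(state.graph, partition, cfg).s_pr
        except UndefinedMeasureError:
            pr = None
    return NetworkReport(
        n_c=n_c, s_max=s_max, s_min=s_min, d_max=d_max, d_min=d_min,
        q=q, l_max=l_max, pr=pr,
    )


def run_preset(
    name: str,
    seeds: Sequence[int],
    eval_cfg: Optional[EvalConfig] = None,
    with_pr: bool = True,
) -> tuple[list[NetworkReport], pd.DataFrame]:
    """Grow the preset once per seed and tabulate the per-seed reports.

    Returns the report objects and a DataFrame with one row per seed plus
    a ``median`` summary row.
    """
    preset = get_preset(name)
    base_cfg = eval_cfg if eval_cfg is not None else EvalConfig()
    reports = []
    for seed in seeds:
        state = grow(preset.params.with_seed(int(seed)))
        if name == "sars_like":
            # structural guarantee of the emulated haplotype network
            assert state.n == 59 and state.graph.number_of_edges() == 59
        cfg = replace(base_cfg, index=preset.index, seed=int(seed))
        reports.append(
            network_report(
                state,
                index=preset.index,
                tree_like=preset.tree_like,
                eval_cfg=cfg,
                with_pr=with_pr,
            )
        )
    rows = [r.to_dict() for r in reports]
    table = pd.DataFrame(rows, index=[f"seed={s}" for s in seeds])
    table.loc["median"] = table.median(numeric_only=True)
    return reports, table


def baseline_ba(k: int, m: int, n: int, seed: Optional[int] = None) -> nx.Graph:
    """Plain preferential-attachment baseline grown from a k-clique.

    Used only for comparison runs: it produces no community structure and,
    unlike the distributive-link model, concentrates links on early hubs.
    """
    if not (1 <= m <= k):
        raise InvalidParameterError(f"need 1 <= m <= k, got m={m}, k={k}")
    if n < k:
        raise InvalidParameterError(f"need n >= k, got n={n}, k={k}")
    if n == k:
        return nx.complete_graph(k)
    return nx.barabasi_albert_graph(
        n, m, seed=np.random.default_rng(seed), initial_graph=nx.complete_graph(k)
    )
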