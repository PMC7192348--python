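"""Network file formats and bundled fixtures.

Two text formats are supported: a plain edge list (two whitespace- or
comma-separated 0-based integer node ids per line, ``#`` comments allowed)
and GraphML carrying the integer node attributes ``community`` (1-based
birth label) and ``birth`` (arrival step).  Round trips are lossless.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional

import networkx as nx

from .errors import ParseError
from .growth import GrowthState

__all__ = [
    "read_network",
    "write_network",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
    "state_to_graph",
    "partition_from_graph",
    "load_karate",
]

FORMATS = ("edgelist", "graphml")


def state_to_graph(state: GrowthState) -> nx.Graph:
    """Copy of the grown graph with ``community``/``birth`` node attributes."""
    g = state.graph.copy()
    nx.set_node_attributes(g, state.node_community, "community")
    nx.set_node_attributes(g, state.node_birth, "birth")
    return g


def partition_from_graph(graph: nx.Graph) -> Optional[list[set[int]]]:
    """Extract the community partition from node attributes, if present."""
    labels = nx.get_node_attributes(graph, "community")
    if len(labels) != graph.number_of_nodes() or not labels:
        return None
    out: dict[int, set[int]] = {}
    for node, lab in labels.items():
        out.setdefault(int(lab), set()).add(node)
    return [out[lab] for lab in sorted(out)]


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise ParseError(f"unknown format {fmt!r}; expected one of {FORMATS}")
        return fmt
    return "graphml" if path.suffix.lower() == ".graphml" else "edgelist"


def read_edgelist(path) -> nx.Graph:
    """Parse an undirected simple-graph edge list; errors carry line numbers."""
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two node ids, got {raw!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: node ids must be integers, got {raw!r}"
                ) from None
            if u == v:
                raise ParseError(f"{path}:{lineno}: self-loop {u}-{v} is not allowed")
            g.add_edge(u, v)
    return g


def write_edgelist(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u} {v}\n")


def read_graphml(path) -> nx.Graph:
    """GraphML reader normalising node ids and label attributes to int."""
    try:
        raw = nx.read_graphml(path)
    except Exception as exc:  # lxml/expat errors carry position info
        raise ParseError(f"{path}: malformed GraphML: {exc}") from exc
    g = nx.Graph()
    try:
        mapping = {v: int(v) for v in raw.nodes()}
    except ValueError:
        mapping = {v: i for i, v in enumerate(raw.nodes())}
    for v, data in raw.nodes(data=True):
        attrs = {}
        for key in ("community", "birth"):
            if key in data:
                try:
                    attrs[key] = int(data[key])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: node {v!r}: attribute {key!r} must be an integer, "
                        f"got {data[key]!r}"
                    ) from None
        g.add_node(mapping[v], **attrs)
    for u, v in raw.edges():
        if mapping[u] == mapping[v]:
            raise ParseError(f"{path}: self-loop at node {u!r} is not allowed")
        g.add_edge(mapping[u], mapping[v])
    return g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_network(path, fmt: Optional[str] = None) -> nx.Graph:
    """Read a network, inferring the format from the extension by default."""
    path = Path(path)
    if _infer_format(path, fmt) == "graphml":
        return read_graphml(path)
    return read_edgelist(path)


def write_network(graph_or_state, path, fmt: Optional[str] = None) -> None:
    """Write a graph or grown state; GraphML keeps community/birth labels."""
    path = Path(path)
    graph = (
        state_to_graph(graph_or_state)
        if isinstance(graph_or_state, GrowthState)
        else graph_or_state
    )
    if _infer_format(path, fmt) == "graphml":
        write_graphml(graph, path)
    else:
        write_edgelist(graph, path)


def load_karate() -> nx.Graph:
    """The Zachary karate club graph (34 nodes, 78 edges), bundled as an
    unweighted edge list."""
    ref = resources.files("comgrow").joinpath("data/karate.edgelist")
    with resources.as_file(ref) as path:
        return read_edgelist(path)
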