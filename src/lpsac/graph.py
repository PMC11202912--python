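"""Graph data model and edge-list I/O.

Graphs are undirected, unweighted and simple, held as :class:`networkx.Graph`
instances whose node labels are opaque strings.  All functions here are thin,
deterministic primitives shared by the similarity measures and the evaluation
protocol: edge-list parsing, canonical pair ordering, neighborhoods, BFS
distances and per-node triangle counts.
"""

from __future__ import annotations

import logging
import math
import re
from typing import IO, Iterable, Iterator, NamedTuple

import networkx as nx

logger = logging.getLogger("lpsac")

__all__ = [
    "NodePair",
    "EdgeListError",
    "node_sort_key",
    "canonical_pair",
    "read_edge_list",
    "write_edge_list",
    "common_neighbors",
    "shortest_path_length",
    "non_adjacent_pairs",
    "triangle_counts",
    "graph_summary",
]

_INT_RE = re.compile(r"[+-]?\d+\Z")


def node_sort_key(label: object) -> tuple:
    """Total order on node labels: numeric-aware for integer-like tokens.

    Labels that parse as integers sort numerically and before all other
    labels, which sort lexicographically.  This makes iteration order over
    graphs with the common 1-based integer labels match human expectation
    while staying deterministic for arbitrary string labels.
    """
    s = str(label)
    if _INT_RE.match(s):
        return (0, int(s), s)
    return (1, math.inf, s)


class NodePair(NamedTuple):
    """An unordered node pair in canonical (sorted) form."""

    u: str
    v: str


def canonical_pair(u: object, v: object) -> NodePair:
    """Return the unique canonical form of the unordered pair {u, v}."""
    u, v = str(u), str(v)
    if u == v:
        raise ValueError(f"a node pair needs two distinct nodes, got {u!r} twice")
    if node_sort_key(v) < node_sort_key(u):
        u, v = v, u
    return NodePair(u, v)


class EdgeListError(ValueError):
    """Raised for malformed, empty or policy-violating edge-list input."""


def _tokenize(line: str) -> list[str]:
    # Auto-detect delimiter: comma-separated if a comma is present,
    # whitespace otherwise.
    if "," in line:
        return [t.strip() for t in line.split(",") if t.strip()]
    return line.split()


def read_edge_list(
    source: IO[str] | str | Iterable[str],
    *,
    comment_char: str = "#",
    deduplicate: bool = True,
    drop_self_loops: bool = True,
) -> nx.Graph:
    """Parse a plain-text edge list into an undirected simple graph.

    Parameters
    ----------
    source
        A file path, an open text stream, or an iterable of lines.  Each
        non-comment, non-blank line holds one edge as two whitespace- or
        comma-separated node tokens; extra tokens are ignored with a warning.
    comment_char
        Lines starting with this character (after stripping) are skipped.
    deduplicate
        Silently collapse repeated edges (logged).  When False a repeated
        edge raises :class:`EdgeListError`.
    drop_self_loops
        Silently drop ``u u`` lines (logged).  When False they raise.

    Returns
    -------
    networkx.Graph
        Simple undirected graph with string node labels.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_edge_list(
                fh,
                comment_char=comment_char,
                deduplicate=deduplicate,
                drop_self_loops=drop_self_loops,
            )

    G = nx.Graph()
    n_dup = n_loops = n_extra = 0
    saw_line = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith(comment_char):
            continue
        saw_line = True
        tokens = _tokenize(line)
        if len(tokens) < 2:
            raise EdgeListError(
                f"line {lineno}: expected two node tokens, got {len(tokens)} ({line!r})"
            )
        if len(tokens) > 2:
            n_extra += 1
        u, v = tokens[0], tokens[1]
        if u == v:
            if not drop_self_loops:
                raise EdgeListError(f"line {lineno}: self-loop {u!r}")
            n_loops += 1
            G.add_node(u)
            continue
        if G.has_edge(u, v):
            if not deduplicate:
                raise EdgeListError(f"line {lineno}: duplicate edge {u!r}-{v!r}")
            n_dup += 1
            continue
        G.add_edge(u, v)

    if not saw_line:
        raise EdgeListError("empty edge list: no edges found")
    if n_extra:
        logger.warning("ignored extra tokens on %d line(s)", n_extra)
    if n_dup:
        logger.warning("dropped %d duplicate edge(s)", n_dup)
    if n_loops:
        logger.warning("dropped %d self-loop(s)", n_loops)
    return G


def write_edge_list(G: nx.Graph, target: IO[str] | str) -> None:
    """Write ``G`` as one canonical ``u v`` line per edge, sorted."""
    if isinstance(target, str):
        with open(target, "w", encoding="utf-8") as fh:
            write_edge_list(G, fh)
        return
    edges = sorted(
        (canonical_pair(u, v) for u, v in G.edges()),
        key=lambda p: (node_sort_key(p.u), node_sort_key(p.v)),
    )
    for u, v in edges:
        target.write(f"{u} {v}\n")


def _require_nodes(G: nx.Graph, *nodes: str) -> None:
    for n in nodes:
        if n not in G:
            raise KeyError(f"node {n!r} not in graph")


def common_neighbors(G: nx.Graph, pair: tuple[str, str]) -> set[str]:
    """Γ(u) ∩ Γ(v): the set of nodes adjacent to both members of the pair."""
    u, v = pair
    _require_nodes(G, u, v)
    return set(G[u]) & set(G[v])


def shortest_path_length(G: nx.Graph, pair: tuple[str, str]) -> float:
    """BFS hop distance between the pair's nodes; ``math.inf`` if disconnected."""
    u, v = pair
    _require_nodes(G, u, v)
    try:
        return nx.shortest_path_length(G, u, v)
    except nx.NetworkXNoPath:
        return math.inf


def non_adjacent_pairs(G: nx.Graph) -> Iterator[NodePair]:
    """Yield every non-adjacent unordered pair once, in canonical order.

    These are the link-prediction candidates: prediction scores are defined
    for pairs that are not already connected.
    """
    nodes = sorted(G.nodes(), key=node_sort_key)
    for i, u in enumerate(nodes):
        adj = G[u]
        for v in nodes[i + 1 :]:
            if v not in adj:
                yield NodePair(u, v)


def triangle_counts(G: nx.Graph) -> dict[str, int]:
    """K_v: the number of edges among Γ(v), i.e. triangles through v."""
    return dict(nx.triangles(G))


def graph_summary(G: nx.Graph) -> dict[str, float]:
    """Basic structural statistics of a graph.

    The diameter is reported on the largest connected component (logged when
    the graph is disconnected).  The average clustering coefficient treats
    degree-0/1 nodes as contributing 0.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot summarize an empty graph")
    degrees = [d for _, d in G.degree()]
    if nx.is_connected(G):
        diam = nx.diameter(G)
    else:
        comp = max(nx.connected_components(G), key=len)
        logger.info(
            "graph is disconnected; diameter reported on the largest "
            "component (%d of %d nodes)",
            len(comp),
            G.number_of_nodes(),
        )
        diam = nx.diameter(G.subgraph(comp)) if len(comp) > 1 else 0
    return {
        "nodes": G.number_of_nodes(),
        "edges": G.number_of_edges(),
        "max_degree": max(degrees),
        "avg_degree": sum(degrees) / len(degrees),
        "diameter": diam,
        "avg_clustering": nx.average_clustering(G, count_zeros=True),
    }
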