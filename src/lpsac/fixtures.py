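"""The published worked-example toy graph, its derivation oracle, and
seeded random-graph generators.

The 8-node/12-edge toy network that the SAC worked example is computed on
is only available as a drawing, so the edge list shipped here is a
reconstruction from the printed constraints: the preferential-attachment
row fixes the degree sequence (each printed product d_v*d_u factors
uniquely over admissible degrees), the worked example names {4, 7} as the
common neighbors of (1, 2), and the six tabulated pairs must be
non-adjacent.  :func:`reconstruct_toy_oracle` re-derives the edge set from
those constraints by exhaustive search and asserts it is the unique graph
reproducing the mutually consistent rows of the published score table.

That table also contains cells inconsistent with *every* graph satisfying
the consistent rows; they are stored with status ``"erratum"`` and the
regression surface asserts they DISAGREE, so a change that silently starts
matching them is flagged.  The KNLP row cannot be checked without the
publication's unstated epsilon and carries status ``"unverifiable"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .graph import NodePair, canonical_pair
from .similarity import rank_pairs

__all__ = [
    "TOY_EDGES",
    "TOY_DEGREES",
    "TABLE2_PAIRS",
    "TABLE2",
    "Table2Cell",
    "toy_graph",
    "printed_match",
    "table2_report",
    "reconstruct_toy_oracle",
    "erdos_renyi",
    "barabasi_albert",
    "stochastic_block",
]

#: Reconstructed edge set of the worked-example graph (unique; see oracle).
TOY_EDGES: tuple[tuple[str, str], ...] = (
    ("1", "4"), ("1", "7"), ("1", "8"),
    ("2", "4"), ("2", "5"), ("2", "7"),
    ("3", "4"), ("3", "6"),
    ("4", "5"), ("4", "6"),
    ("5", "6"), ("5", "8"),
)

#: Degree sequence forced by the preferential-attachment row.
TOY_DEGREES: dict[str, int] = {
    "1": 3, "2": 3, "3": 2, "4": 5, "5": 4, "6": 3, "7": 2, "8": 2,
}

#: The six non-adjacent pairs tabulated in the worked example.
TABLE2_PAIRS: tuple[NodePair, ...] = tuple(
    canonical_pair(*p)
    for p in (("1", "2"), ("2", "3"), ("2", "6"), ("4", "7"), ("4", "8"), ("5", "7"))
)

#: Printed worked-example scores: measure -> {pair: (printed value, status)}.
#: status: "consistent" cells are reproduced by the reconstruction;
#: "erratum" cells provably disagree with it; "unverifiable" cells depend
#: on an unstated parameter.
TABLE2: dict[str, dict[NodePair, tuple[float, str]]] = {
    "sac_d": {},
    "sac_b": {},
    "sac_c": {},
    "sac_cc": {},
    "cn": {},
    "jc": {},
    "aa": {},
    "ra": {},
    "pa": {},
    "ccpa": {},
    "knlp": {},
}

_TABLE2_ROWS = {
    "sac_d": ([1, 1, 2, 2, 2, 1], []),
    "sac_b": ([1, 1, 2, 2, 1, 1], [("4", "8")]),
    "sac_c": ([2, 1, 2, 1, 1, 1], [("1", "2"), ("4", "7"), ("4", "8")]),
    "sac_cc": ([0, 0, 1, 0, 2, 0], [("4", "7"), ("4", "8"), ("5", "7")]),
    "cn": ([2, 1, 2, 2, 2, 2], [("5", "7")]),
    "jc": ([0.5, 0.2, 0.5, 0.4, 0.4, 0.2], []),
    "aa": ([2, 0.6, 1.3, 1.8, 1.6, 0.9], []),
    "ra": ([0.7, 0.2, 0.4, 0.6, 0.5, 0.3], []),
    "pa": ([9, 6, 9, 10, 10, 8], []),
    "ccpa": ([2.4, 1.5, 2.4, 2, 2.4, 1.5], [("2", "3"), ("4", "7"), ("5", "7")]),
    "knlp": ([0.9, 0.4, 0.7, 2.3, 0.5, 1.2], None),  # None -> unverifiable row
}

for _measure, (_values, _errata) in _TABLE2_ROWS.items():
    for _pair, _val in zip(TABLE2_PAIRS, _values):
        if _errata is None:
            _status = "unverifiable"
        elif tuple(_pair) in [tuple(canonical_pair(*e)) for e in _errata]:
            _status = "erratum"
        else:
            _status = "consistent"
        TABLE2[_measure][_pair] = (float(_val), _status)


def toy_graph() -> nx.Graph:
    """Return the reconstructed 8-node, 12-edge worked-example graph."""
    G = nx.Graph()
    G.add_nodes_from(str(i) for i in range(1, 9))
    G.add_edges_from(TOY_EDGES)
    return G


def printed_match(value: float, printed: float) -> bool:
    """Does ``value`` display as ``printed`` at one decimal?

    The published table mixes round-half-away-from-zero with plain
    truncation (e.g. 0.667 printed as 0.6), so a computed value matches if
    either one-decimal rendering equals the printed number.  A tiny epsilon
    guards against binary-float artifacts like 0.7*10 == 6.999...
    """
    rounded = math.floor(value * 10 + 0.5 + 1e-9) / 10
    truncated = math.floor(value * 10 + 1e-9) / 10
    return math.isclose(rounded, printed, abs_tol=1e-9) or math.isclose(
        truncated, printed, abs_tol=1e-9
    )


@dataclass(frozen=True)
class Table2Cell:
    """One worked-example cell compared against the package's computation."""

    measure: str
    pair: NodePair
    printed: float
    computed: float
    status: str
    match: bool


def table2_report(alpha: float = 0.8) -> list[Table2Cell]:
    """Recompute every worked-example cell and compare with the printed value.

    For ``"consistent"`` cells the computation should match the print (one
    decimal, round-or-truncate); for ``"erratum"`` cells it should not; for
    ``"unverifiable"`` cells (KNLP: unstated epsilon) no expectation holds.
    """
    G = toy_graph()
    cells: list[Table2Cell] = []
    for measure, row in TABLE2.items():
        ranking = rank_pairs(G, measure, alpha=alpha, pairs=list(row))
        computed = {sp.pair: sp.score for sp in ranking}
        for pair, (printed, status) in row.items():
            value = computed[pair]
            cells.append(
                Table2Cell(
                    measure=measure,
                    pair=pair,
                    printed=printed,
                    computed=value,
                    status=status,
                    match=printed_match(value, printed),
                )
            )
    return cells


# ---------------------------------------------------------------------------
# Reconstruction oracle
# ---------------------------------------------------------------------------

def _degree_valid_edge_sets(
    require_common_neighbors: bool = True,
) -> list[frozenset[frozenset[str]]]:
    """All 12-edge graphs on nodes 1..8 satisfying the hard constraints.

    Constraints: the forced degree sequence, non-adjacency of the six
    tabulated pairs, and (optionally) common neighbors of (1,2) being
    exactly {4, 7}.  Exhaustive depth-first search with degree pruning.
    """
    nodes = [str(i) for i in range(1, 9)]
    forbidden = {frozenset(p) for p in TABLE2_PAIRS}
    candidates = [
        frozenset((u, v))
        for i, u in enumerate(nodes)
        for v in nodes[i + 1 :]
        if frozenset((u, v)) not in forbidden
    ]
    target = dict(TOY_DEGREES)
    forced: set[frozenset[str]] = set()
    if require_common_neighbors:
        # Γ(1) ∩ Γ(2) = {4, 7}: those four edges exist, and no other node
        # may neighbor both 1 and 2.
        forced = {
            frozenset(e) for e in (("1", "4"), ("1", "7"), ("2", "4"), ("2", "7"))
        }

    # remaining degree capacity per node, per candidate-suffix, for pruning
    results: list[frozenset[frozenset[str]]] = []
    n_edges = 12

    def violates_cn(chosen: set[frozenset[str]]) -> bool:
        if not require_common_neighbors:
            return False
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for e in chosen:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        return (adj["1"] & adj["2"]) != {"4", "7"}

    deg = {n: 0 for n in nodes}
    chosen: set[frozenset[str]] = set()
    for e in forced:
        chosen.add(e)
        for n in e:
            deg[n] += 1

    free = [e for e in candidates if e not in forced]

    # incident capacity suffix: for pruning, count of remaining free edges
    # touching each node from index i onward
    suffix_cap: list[dict[str, int]] = [dict.fromkeys(nodes, 0) for _ in range(len(free) + 1)]
    for i in range(len(free) - 1, -1, -1):
        cap = dict(suffix_cap[i + 1])
        for n in free[i]:
            cap[n] += 1
        suffix_cap[i] = cap

    def dfs(i: int) -> None:
        if len(chosen) == n_edges:
            if all(deg[n] == target[n] for n in nodes) and not violates_cn(chosen):
                results.append(frozenset(chosen))
            return
        if i == len(free) or len(chosen) + (len(free) - i) < n_edges:
            return
        # prune: every node must still be able to reach its target degree
        for n in nodes:
            if deg[n] + suffix_cap[i][n] < target[n]:
                return
        e = free[i]
        a, b = tuple(e)
        if deg[a] < target[a] and deg[b] < target[b]:
            chosen.add(e)
            deg[a] += 1
            deg[b] += 1
            dfs(i + 1)
            chosen.discard(e)
            deg[a] -= 1
            deg[b] -= 1
        dfs(i + 1)

    dfs(0)
    return results


#: Number of worked-example cells with status "consistent" (all verifiable
#: rows; KNLP excluded).  The fully consistent basic rows (jc/aa/ra/pa/
#: sac_d + cn minus its bad cell) do not pin the graph uniquely — a second
#: degree-valid graph reproduces all 35 of them but misses consistent
#: SAC_B/SAC_CC cells — so the oracle objective spans every consistent cell.
N_CONSISTENT_CELLS = sum(
    1 for row in TABLE2.values() for _, status in row.values() if status == "consistent"
)


def _row_match_count(G: nx.Graph) -> int:
    """Consistent worked-example cells reproduced by graph ``G``.

    Scores the six tabulated pairs under every verifiable measure and
    counts one-decimal display matches on the cells whose printed values
    are mutually consistent.  Maximum is :data:`N_CONSISTENT_CELLS`.
    """
    count = 0
    for measure, row in TABLE2.items():
        if all(status != "consistent" for _, status in row.values()):
            continue
        ranking = rank_pairs(G, measure, pairs=list(TABLE2_PAIRS))
        computed = {sp.pair: sp.score for sp in ranking}
        for pair, (printed, status) in row.items():
            if status == "consistent" and printed_match(computed[pair], printed):
                count += 1
    return count


def reconstruct_toy_oracle(
    require_common_neighbors: bool = True,
) -> frozenset[NodePair]:
    """Re-derive the toy edge set from the printed constraints.

    Enumerates every graph satisfying the degree sequence and non-adjacency
    constraints (optionally also the stated common neighbors of (1,2)),
    scores each against the mutually consistent table rows, and returns the
    unique graph reproducing all 35 checkable cells.

    Raises
    ------
    AssertionError
        If no candidate, or more than one, attains a perfect row match —
        which would falsify the packaged fixture.
    """
    best: list[frozenset[frozenset[str]]] = []
    best_count = -1
    for edge_set in _degree_valid_edge_sets(require_common_neighbors):
        G = nx.Graph()
        G.add_nodes_from(str(i) for i in range(1, 9))
        G.add_edges_from(tuple(e) for e in edge_set)
        c = _row_match_count(G)
        if c > best_count:
            best, best_count = [edge_set], c
        elif c == best_count:
            best.append(edge_set)
    assert best_count == N_CONSISTENT_CELLS, (
        f"no candidate graph reproduces all {N_CONSISTENT_CELLS} consistent "
        f"cells (best: {best_count})"
    )
    assert len(best) == 1, f"reconstruction is not unique: {len(best)} maximizers"
    return frozenset(canonical_pair(*e) for e in best[0])


# ---------------------------------------------------------------------------
# Seeded random-graph generators (property-test and benchmark inputs)
# ---------------------------------------------------------------------------

def _as_str_labels(G: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(G, {n: str(n) for n in G.nodes()})


def erdos_renyi(n: int, p: float, seed: int) -> nx.Graph:
    """G(n, p) random graph, seeded, string node labels."""
    if n < 0 or not 0.0 <= p <= 1.0:
        raise ValueError(f"invalid Erdos-Renyi parameters n={n}, p={p}")
    return _as_str_labels(nx.gnp_random_graph(n, p, seed=seed))


def barabasi_albert(n: int, attach_m: int, seed: int) -> nx.Graph:
    """Preferential-attachment graph: n nodes, attach_m edges per arrival."""
    if not 1 <= attach_m < n:
        raise ValueError(f"need 1 <= attach_m < n, got attach_m={attach_m}, n={n}")
    return _as_str_labels(nx.barabasi_albert_graph(n, attach_m, seed=seed))


def stochastic_block(
    sizes: list[int], p_in: float, p_out: float, seed: int
) -> nx.Graph:
    """Planted-community graph: within-block density p_in, between p_out."""
    if min(sizes, default=0) < 1:
        raise ValueError("block sizes must be positive")
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError(f"need 0 <= p_out <= p_in <= 1, got p_in={p_in}, p_out={p_out}")
    k = len(sizes)
    p = [[p_in if i == j else p_out for j in range(k)] for i in range(k)]
    return _as_str_labels(nx.stochastic_block_model(sizes, p, seed=seed))
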