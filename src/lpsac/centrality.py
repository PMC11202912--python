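"""Node centralities and the graph-average centrality.

Five centralities are provided: degree and clustering coefficient (local),
closeness and betweenness (global), and eigenvector centrality (used by the
KNLP similarity index).  Each returns a :class:`CentralityVector` carrying
the per-node scores together with the normalization conventions used, so
downstream consumers (notably the average-centrality threshold test) can
document exactly what was computed.

The SAC family only compares centralities against their own graph average,
a scale-invariant test, so the convention choices here (degree denominator,
betweenness normalization) never change SAC outputs — only reported values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import node_sort_key

__all__ = [
    "CentralityVector",
    "AverageCentrality",
    "CENTRALITY_KINDS",
    "degree_centrality",
    "clustering_coefficient",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "average_centrality",
    "centrality_vector",
]

CENTRALITY_KINDS = ("degree", "betweenness", "closeness", "clustering", "eigenvector")


@dataclass(frozen=True)
class CentralityVector:
    """Per-node real scores of one centrality kind.

    Attributes
    ----------
    kind
        One of :data:`CENTRALITY_KINDS`.
    scores
        Mapping node label -> score C(v); exactly one entry per graph node.
    convention
        Normalization choices that produced the scores (e.g. the degree
        denominator), recorded for provenance.
    """

    kind: str
    scores: dict[str, float]
    convention: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CENTRALITY_KINDS:
            raise ValueError(
                f"unknown centrality kind {self.kind!r}; expected one of {CENTRALITY_KINDS}"
            )
        if not self.scores:
            raise ValueError("centrality vector has no scores")

    def __getitem__(self, node: str) -> float:
        return self.scores[node]


@dataclass(frozen=True)
class AverageCentrality:
    """A_C(G): the arithmetic mean of one centrality over all graph nodes."""

    kind: str
    value: float


def _vector(G: nx.Graph, kind: str, scores: dict, convention: dict) -> CentralityVector:
    if set(scores) != set(G.nodes()):
        raise ValueError("centrality scores do not cover the graph's node set")
    return CentralityVector(kind=kind, scores=dict(scores), convention=convention)


def degree_centrality(G: nx.Graph, denominator: str = "N") -> CentralityVector:
    """Degree centrality d_v divided by ``N`` or ``N-1``.

    The worked-example convention is ``N`` (scores then average to 2m/N^2);
    ``N-1`` is the textbook fraction of possible neighbors.  The SAC
    threshold test is invariant to this choice.
    """
    if denominator not in ("N", "N-1"):
        raise ValueError("denominator must be 'N' or 'N-1'")
    n = G.number_of_nodes()
    den = n if denominator == "N" else n - 1
    if den <= 0:
        raise ValueError(f"cannot use denominator {denominator} with N={n}")
    scores = {v: d / den for v, d in G.degree()}
    return _vector(G, "degree", scores, {"denominator": denominator})


def clustering_coefficient(G: nx.Graph) -> CentralityVector:
    """Local clustering coefficient 2K_v / (d_v(d_v-1)); 0 for degree < 2."""
    return _vector(G, "clustering", nx.clustering(G), {"degree_lt_2": 0.0})


def closeness_centrality(G: nx.Graph) -> CentralityVector:
    """Closeness centrality, reachable-set variant.

    For node v with R_v reachable nodes, (R_v-1)/Σ D_{v,u} scaled by
    (R_v-1)/(N-1).  On a connected graph this is exactly (N-1)/Σ D_{v,u};
    on disconnected graphs it degrades gracefully instead of dividing by an
    undefined sum.  Isolated nodes score 0.
    """
    scores = nx.closeness_centrality(G, wf_improved=True)
    return _vector(G, "closeness", scores, {"variant": "reachable-scaled"})


def betweenness_centrality(G: nx.Graph, normalized: bool = True) -> CentralityVector:
    """Shortest-path betweenness Σ_{s≠t≠v} σ_{s,t}(v)/σ_{s,t} over unordered pairs.

    Computed with Brandes accumulation; when ``normalized``, divided by
    (N-1)(N-2)/2.
    """
    scores = nx.betweenness_centrality(G, normalized=normalized)
    return _vector(G, "betweenness", scores, {"normalized": normalized})


def eigenvector_centrality(
    G: nx.Graph, tol: float = 1e-6, max_iter: int = 1000
) -> CentralityVector:
    """Principal-eigenvector centrality by power iteration, unit L2 norm.

    Iterates x <- (I + A) x / ||(I + A) x||_2 from a uniform start until
    the residual ||x_{k+1} - x_k||_2 falls below ``tol``.  The identity
    shift leaves the eigenvectors of A unchanged but separates the
    dominant eigenvalue from its negative, so bipartite graphs (whose
    +/-lambda pair defeats the unshifted iteration) converge too.  Scores
    are non-negative.

    Raises
    ------
    RuntimeError
        If the iteration has not converged after ``max_iter`` steps; the
        message reports the final residual.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("eigenvector centrality of an empty graph")
    nodes = sorted(G.nodes(), key=node_sort_key)
    A = nx.to_scipy_sparse_array(G, nodelist=nodes, dtype=float)
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    residual = np.inf
    for _ in range(max_iter):
        y = x + A @ x
        y = y / np.linalg.norm(y)
        residual = float(np.linalg.norm(y - x))
        x = y
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} > tol {tol:.1e})"
        )
    scores = {v: float(s) for v, s in zip(nodes, np.abs(x))}
    return _vector(G, "eigenvector", scores, {"norm": "L2", "tol": tol})


def average_centrality(cv: CentralityVector) -> AverageCentrality:
    """A_C(G): arithmetic mean of the centrality over all N nodes."""
    if not cv.scores:
        raise ValueError("cannot average an empty centrality vector")
    return AverageCentrality(kind=cv.kind, value=sum(cv.scores.values()) / len(cv.scores))


def centrality_vector(G: nx.Graph, kind: str, **options) -> CentralityVector:
    """Dispatch to the centrality of the given kind with keyword options."""
    funcs = {
        "degree": degree_centrality,
        "clustering": clustering_coefficient,
        "closeness": closeness_centrality,
        "betweenness": betweenness_centrality,
        "eigenvector": eigenvector_centrality,
    }
    if kind not in funcs:
        raise ValueError(f"unknown centrality kind {kind!r}; expected one of {CENTRALITY_KINDS}")
    return funcs[kind](G, **options)
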