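"""Similarity indices for link prediction.

Implements eleven pairwise similarity scores over non-adjacent node pairs:

* the five classical local indices — common neighbors (CN), Jaccard (JC),
  preferential attachment (PA), resource allocation (RA), Adamic–Adar (AA);
* two centrality-flavoured indices — CCPA (a convex blend of common
  neighbors and an N/distance closeness term, weight alpha) and KNLP (the
  ratio of the pair's eigenvector-centrality sum to its clustering-
  coefficient sum plus a small epsilon);
* the SAC family (Similarity based on Average Centrality): the number of
  common neighbors whose centrality is at least the graph-average
  centrality, instantiated with degree (sac_d), betweenness (sac_b),
  closeness (sac_c) and clustering-coefficient (sac_cc) centrality.

The SAC threshold is inclusive (>=): a common neighbor sitting exactly at
the average counts.  Because the test compares a centrality only against
its own mean, any uniform rescaling of the centrality (degree denominator,
betweenness normalization) leaves every SAC score unchanged.

All scores are symmetric in the pair and defined for non-adjacent pairs;
scoring an adjacent pair raises unless explicitly overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import networkx as nx

from .centrality import AverageCentrality, CentralityVector, average_centrality, centrality_vector
from .graph import (
    NodePair,
    canonical_pair,
    common_neighbors,
    logger,
    node_sort_key,
    non_adjacent_pairs,
    shortest_path_length,
)

__all__ = [
    "ScoredPair",
    "SACContext",
    "MEASURES",
    "SAC_KINDS",
    "DEFAULT_ALPHA",
    "DEFAULT_EPSILON",
    "score_cn",
    "score_jc",
    "score_pa",
    "score_ra",
    "score_aa",
    "score_ccpa",
    "score_knlp",
    "score_sac",
    "build_sac_context",
    "rank_pairs",
    "write_scores",
]

#: Mapping from SAC measure id to the centrality kind it thresholds on.
SAC_KINDS = {
    "sac_d": "degree",
    "sac_b": "betweenness",
    "sac_c": "closeness",
    "sac_cc": "clustering",
}

MEASURES = ("cn", "jc", "pa", "ra", "aa", "ccpa", "knlp") + tuple(SAC_KINDS)

#: CCPA mixing weight reproducing the published worked example.
DEFAULT_ALPHA = 0.8
#: KNLP division-by-zero guard.
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class ScoredPair:
    """A canonical non-adjacent node pair with its similarity score."""

    pair: NodePair
    score: float
    measure: str


@dataclass(frozen=True)
class SACContext:
    """A centrality vector paired with its graph average, same kind.

    Built once per graph and reused across pairs; construction re-checks
    that the stored average is the mean of the stored scores.

    ``qualifying`` is the set of nodes passing the inclusive threshold
    C(v) >= A_C(G).  For centralities with rational values (degree,
    clustering coefficient) :func:`build_sac_context` precomputes it with
    exact integer/fraction arithmetic, so nodes sitting exactly at the
    average — which the worked example shows must count — are never lost
    to floating-point rounding of the mean.  When not supplied it is
    derived from the floating-point scores.
    """

    centrality: CentralityVector
    average: AverageCentrality
    qualifying: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.centrality.kind != self.average.kind:
            raise ValueError(
                f"centrality kind {self.centrality.kind!r} does not match "
                f"average kind {self.average.kind!r}"
            )
        mean = sum(self.centrality.scores.values()) / len(self.centrality.scores)
        if abs(mean - self.average.value) > 1e-12:
            raise ValueError("stored average is not the mean of the centrality scores")
        if self.qualifying is None:
            object.__setattr__(
                self,
                "qualifying",
                frozenset(
                    v for v, s in self.centrality.scores.items() if s >= self.average.value
                ),
            )


def _checked_pair(G: nx.Graph, pair: tuple[str, str], allow_adjacent: bool) -> NodePair:
    p = canonical_pair(*pair)
    for n in p:
        if n not in G:
            raise KeyError(f"node {n!r} not in graph")
    if not allow_adjacent and G.has_edge(p.u, p.v):
        raise ValueError(
            f"pair {p.u!r}-{p.v!r} is adjacent; similarity scores are defined for "
            "non-adjacent pairs (pass allow_adjacent=True to score it anyway)"
        )
    return p


def score_cn(G: nx.Graph, pair, *, allow_adjacent: bool = False) -> ScoredPair:
    """Common-neighbor count |Γ(u) ∩ Γ(v)|."""
    p = _checked_pair(G, pair, allow_adjacent)
    return ScoredPair(p, float(len(common_neighbors(G, p))), "cn")


def score_jc(G: nx.Graph, pair, *, allow_adjacent: bool = False) -> ScoredPair:
    """Jaccard coefficient |Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v)|; 0 if both isolated."""
    p = _checked_pair(G, pair, allow_adjacent)
    union = set(G[p.u]) | set(G[p.v])
    if not union:
        logger.info("jc(%s, %s): both nodes isolated, score 0 by convention", p.u, p.v)
        return ScoredPair(p, 0.0, "jc")
    return ScoredPair(p, len(common_neighbors(G, p)) / len(union), "jc")


def score_pa(G: nx.Graph, pair, *, allow_adjacent: bool = False) -> ScoredPair:
    """Preferential attachment d_u * d_v."""
    p = _checked_pair(G, pair, allow_adjacent)
    return ScoredPair(p, float(G.degree(p.u) * G.degree(p.v)), "pa")


def score_ra(G: nx.Graph, pair, *, allow_adjacent: bool = False) -> ScoredPair:
    """Resource allocation: sum of 1/d_r over common neighbors r."""
    p = _checked_pair(G, pair, allow_adjacent)
    return ScoredPair(p, sum(1.0 / G.degree(r) for r in common_neighbors(G, p)), "ra")


def score_aa(G: nx.Graph, pair, *, allow_adjacent: bool = False) -> ScoredPair:
    """Adamic–Adar: sum of 1/ln(d_r) over common neighbors r (natural log)."""
    p = _checked_pair(G, pair, allow_adjacent)
    return ScoredPair(p, sum(1.0 / math.log(G.degree(r)) for r in common_neighbors(G, p)), "aa")


def score_ccpa(
    G: nx.Graph,
    pair,
    *,
    alpha: float = DEFAULT_ALPHA,
    allow_adjacent: bool = False,
    _dist: float | None = None,
) -> ScoredPair:
    """CCPA: alpha * CN + (1 - alpha) * N / D, with D the BFS distance.

    For a disconnected pair the second term vanishes (the D -> inf limit).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    p = _checked_pair(G, pair, allow_adjacent)
    d = shortest_path_length(G, p) if _dist is None else _dist
    closeness_term = 0.0 if math.isinf(d) or d == 0 else G.number_of_nodes() / d
    score = alpha * len(common_neighbors(G, p)) + (1.0 - alpha) * closeness_term
    return ScoredPair(p, score, "ccpa")


def score_knlp(
    G: nx.Graph,
    pair,
    cs: CentralityVector,
    cc: CentralityVector,
    *,
    epsilon: float = DEFAULT_EPSILON,
    allow_adjacent: bool = False,
) -> ScoredPair:
    """KNLP: (CS_u + CS_v) / (CC_u + CC_v + epsilon).

    ``cs`` is the eigenvector-centrality vector and ``cc`` the clustering-
    coefficient vector, both computed on ``G``.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if cs.kind != "eigenvector" or cc.kind != "clustering":
        raise ValueError(
            f"knlp needs an eigenvector and a clustering vector, got {cs.kind!r}/{cc.kind!r}"
        )
    p = _checked_pair(G, pair, allow_adjacent)
    score = (cs[p.u] + cs[p.v]) / (cc[p.u] + cc[p.v] + epsilon)
    return ScoredPair(p, score, "knlp")


def score_sac(
    G: nx.Graph, pair, ctx: SACContext, *, allow_adjacent: bool = False
) -> ScoredPair:
    """SAC: common neighbors whose centrality is >= the graph average.

    The count is over x in Γ(u) ∩ Γ(v) with C(x) >= A_C(G); the comparison
    is inclusive.  Always 0 <= SAC <= CN.
    """
    p = _checked_pair(G, pair, allow_adjacent)
    measure = {v: k for k, v in SAC_KINDS.items()}.get(ctx.centrality.kind, "sac")
    count = sum(1 for x in common_neighbors(G, p) if x in ctx.qualifying)
    return ScoredPair(p, float(count), measure)


def build_sac_context(G: nx.Graph, kind: str, **centrality_options) -> SACContext:
    """Build the centrality + average context for one SAC measure.

    ``kind`` is a centrality kind or a SAC measure id (``sac_d`` etc.).
    Degree and clustering thresholds are resolved with exact arithmetic:
    d_v >= average degree reduces to the integer test d_v * N >= 2m
    (independent of the degree-centrality denominator), and clustering
    coefficients are compared as exact fractions.
    """
    kind = SAC_KINDS.get(kind, kind)
    cv = centrality_vector(G, kind, **centrality_options)
    qualifying: frozenset[str] | None = None
    if kind == "degree":
        two_m = 2 * G.number_of_edges()
        n = G.number_of_nodes()
        qualifying = frozenset(v for v, d in G.degree() if d * n >= two_m)
    elif kind == "clustering":
        tri = nx.triangles(G)
        exact = {
            v: Fraction(2 * tri[v], d * (d - 1)) if d >= 2 else Fraction(0)
            for v, d in G.degree()
        }
        avg = sum(exact.values(), Fraction(0)) / len(exact)
        qualifying = frozenset(v for v, s in exact.items() if s >= avg)
    return SACContext(centrality=cv, average=average_centrality(cv), qualifying=qualifying)


def _pair_order_key(p: NodePair) -> tuple:
    return (node_sort_key(p.u), node_sort_key(p.v))


def rank_pairs(
    G: nx.Graph,
    measure: str,
    *,
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
    pairs: Iterable[tuple[str, str]] | None = None,
    allow_adjacent: bool = False,
) -> list[ScoredPair]:
    """Score candidate pairs under one measure and rank them.

    By default all non-adjacent pairs of ``G`` are scored.  Any centrality
    context the measure needs (SAC averages, KNLP vectors, CCPA distances)
    is computed once for the whole call.  The result is sorted by
    descending score, ties broken by canonical pair order, so rankings are
    deterministic across platforms.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; valid measures: {', '.join(MEASURES)}")

    if pairs is None:
        candidates = list(non_adjacent_pairs(G))
    else:
        candidates = [canonical_pair(*p) for p in pairs]

    scorer: Callable[[NodePair], ScoredPair]
    if measure in SAC_KINDS:
        ctx = build_sac_context(G, measure)
        scorer = lambda p: score_sac(G, p, ctx, allow_adjacent=allow_adjacent)
    elif measure == "knlp":
        cs = centrality_vector(G, "eigenvector")
        cc = centrality_vector(G, "clustering")
        scorer = lambda p: score_knlp(
            G, p, cs, cc, epsilon=epsilon, allow_adjacent=allow_adjacent
        )
    elif measure == "ccpa":
        # One BFS per source beats one BFS per pair when candidates are dense.
        dist = dict(nx.all_pairs_shortest_path_length(G))
        scorer = lambda p: score_ccpa(
            G,
            p,
            alpha=alpha,
            allow_adjacent=allow_adjacent,
            _dist=dist.get(p.u, {}).get(p.v, math.inf),
        )
    else:
        simple = {"cn": score_cn, "jc": score_jc, "pa": score_pa, "ra": score_ra, "aa": score_aa}
        fn = simple[measure]
        scorer = lambda p: fn(G, p, allow_adjacent=allow_adjacent)

    scored = [scorer(p) for p in candidates]
    scored.sort(key=lambda sp: (-sp.score, _pair_order_key(sp.pair)))
    return scored


def write_scores(scored: Sequence[ScoredPair], target) -> None:
    """Write a ranking as TSV with header ``u\\tv\\tscore``."""
    if isinstance(target, str):
        with open(target, "w", encoding="utf-8") as fh:
            write_scores(scored, fh)
        return
    target.write("u\tv\tscore\n")
    for sp in scored:
        target.write(f"{sp.pair.u}\t{sp.pair.v}\t{sp.score:.10g}\n")
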