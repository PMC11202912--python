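"""Hold-out evaluation protocol: edge split, labeling, AUROC/AUPR, top-k.

The protocol mirrors the standard link-prediction benchmark: a random
fraction of edges (default 20%) is removed as test positives, every pair
non-adjacent in the residual training graph becomes a candidate, candidates
are scored by a similarity measure, and the ranking is summarized by AUROC
(midrank / Mann–Whitney formulation) and AUPR (average precision).  Metrics
can additionally be restricted to the k top-scored candidates.

One split per seed is shared across all measures so comparisons are paired.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import networkx as nx
from scipy.stats import rankdata

from .graph import NodePair, canonical_pair, logger, node_sort_key, non_adjacent_pairs
from .similarity import DEFAULT_ALPHA, DEFAULT_EPSILON, MEASURES, rank_pairs

__all__ = [
    "EdgeSplit",
    "LabeledScores",
    "MetricsReport",
    "split_edges",
    "label_candidates",
    "score_candidates",
    "auroc",
    "aupr",
    "topk_metrics",
    "run_experiment",
]


@dataclass(frozen=True)
class EdgeSplit:
    """A train graph plus the held-out positive test edges, with provenance."""

    train: nx.Graph
    test_edges: frozenset[NodePair]
    seed: int
    fraction: float


@dataclass(frozen=True)
class LabeledScores:
    """Scored candidate pairs with positive/negative labels.

    Candidates are the pairs non-adjacent in the training graph; a candidate
    is positive iff it is a held-out test edge.  Entries are ordered by
    descending score with ties broken by canonical pair order, which fixes
    every rank-based quantity computed from them.
    """

    entries: tuple[tuple[NodePair, float, bool], ...]

    @property
    def n_pos(self) -> int:
        return sum(1 for *_, lab in self.entries if lab)

    @property
    def n_neg(self) -> int:
        return len(self.entries) - self.n_pos


@dataclass(frozen=True)
class MetricsReport:
    """AUROC/AUPR for one measure at one k (or unrestricted, k='all')."""

    measure: str
    k: int | str
    auroc: float | None
    aupr: float | None
    n_pos: int
    n_neg: int
    seed: int
    fraction: float
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def split_edges(G: nx.Graph, fraction: float, seed: int) -> EdgeSplit:
    """Hold out ``floor(fraction * m)`` (at least 1) edges uniformly at random.

    Deterministic for fixed (graph, fraction, seed).  Removal may disconnect
    the training graph; that is allowed and logged.  All nodes are retained.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"test fraction must lie in (0, 1), got {fraction}")
    m = G.number_of_edges()
    if m < 2:
        raise ValueError(f"need at least 2 edges to split, got {m}")
    n_test = max(1, math.floor(fraction * m))
    edges = sorted(
        (canonical_pair(u, v) for u, v in G.edges()),
        key=lambda p: (node_sort_key(p.u), node_sort_key(p.v)),
    )
    rng = random.Random(seed)
    test = frozenset(rng.sample(edges, n_test))
    train = nx.Graph()
    train.add_nodes_from(G.nodes())
    train.add_edges_from(e for e in edges if e not in test)
    if not nx.is_connected(train) and nx.is_connected(G):
        logger.info("edge holdout disconnected the training graph (seed %d)", seed)
    return EdgeSplit(train=train, test_edges=test, seed=seed, fraction=fraction)


def label_candidates(split: EdgeSplit) -> list[tuple[NodePair, bool]]:
    """Candidate pairs of the training graph with positive/negative labels.

    Candidates are all pairs non-adjacent in the train graph; positives are
    exactly the held-out edges.  n_pos + n_neg = C(N,2) - m_train.
    """
    out = [(p, p in split.test_edges) for p in non_adjacent_pairs(split.train)]
    if not out:
        raise ValueError("no non-adjacent pairs in the training graph: nothing to predict")
    return out


def score_candidates(
    split: EdgeSplit,
    measure: str,
    *,
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
) -> LabeledScores:
    """Score the training graph's candidate pairs and attach labels."""
    labels = dict(label_candidates(split))
    ranking = rank_pairs(split.train, measure, alpha=alpha, epsilon=epsilon)
    entries = tuple((sp.pair, sp.score, labels[sp.pair]) for sp in ranking)
    return LabeledScores(entries=entries)


def _split_scores(ls: LabeledScores) -> tuple[list[float], list[float]]:
    pos = [s for _, s, lab in ls.entries if lab]
    neg = [s for _, s, lab in ls.entries if not lab]
    return pos, neg


def auroc(ls: LabeledScores) -> float:
    """AUROC via the midrank (Mann–Whitney) statistic.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg), which is
    the trapezoidal area under the empirical ROC curve.
    """
    pos, neg = _split_scores(ls)
    if not pos or not neg:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = rankdata(pos + neg)  # midranks for ties
    rank_sum_pos = float(sum(ranks[: len(pos)]))
    u = rank_sum_pos - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def aupr(ls: LabeledScores) -> float:
    """AUPR as average precision over the deterministic ranking.

    Sum of precision@rank over the ranks where positives sit, divided by the
    number of positives; ties follow the entries' canonical order.
    """
    if not any(lab for *_, lab in ls.entries):
        raise ValueError("AUPR needs at least one positive")
    total = 0.0
    tp = 0
    for rank, (_, _, lab) in enumerate(ls.entries, start=1):
        if lab:
            tp += 1
            total += tp / rank
    return total / tp


def topk_metrics(
    ls: LabeledScores,
    k: int | str,
    *,
    measure: str = "",
    seed: int = -1,
    fraction: float = float("nan"),
) -> MetricsReport:
    """AUROC/AUPR restricted to the k top-scored candidates.

    ``k='all'`` (or k >= candidate count, clamped with a warning) gives the
    unrestricted metrics.  A single-class top-k subset yields flagged null
    metrics rather than an exception — inevitable at small k.
    """
    n = len(ls.entries)
    if k == "all":
        k_eff = n
    else:
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k > n:
            logger.warning("k=%d exceeds the %d candidates; clamping", k, n)
        k_eff = min(k, n)
    sub = LabeledScores(entries=ls.entries[:k_eff])
    note = ""
    if sub.n_pos == 0 or sub.n_neg == 0:
        note = f"single-class top-{k_eff} subset (n_pos={sub.n_pos}, n_neg={sub.n_neg})"
        roc = None
        pr = 1.0 if sub.n_pos and not sub.n_neg else None
    else:
        roc = auroc(sub)
        pr = aupr(sub)
    return MetricsReport(
        measure=measure,
        k=k,
        auroc=roc,
        aupr=pr,
        n_pos=sub.n_pos,
        n_neg=sub.n_neg,
        seed=seed,
        fraction=fraction,
        note=note,
    )


def run_experiment(
    G: nx.Graph,
    measures: Sequence[str],
    *,
    fraction: float = 0.2,
    seed: int = 0,
    k_grid: Iterable[int | str] = ("all",),
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
) -> list[MetricsReport]:
    """Run the full holdout protocol: one report per (measure, k).

    A single split per seed is shared by all measures, so cross-measure
    comparisons are paired.  Include ``"all"`` in ``k_grid`` to report the
    unrestricted metrics alongside any top-k restrictions.
    """
    measures = list(measures)
    if not measures:
        raise ValueError("need at least one measure to evaluate")
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}; valid measures: {', '.join(MEASURES)}")
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")

    split = split_edges(G, fraction, seed)
    reports: list[MetricsReport] = []
    for m in measures:
        try:
            ls = score_candidates(split, m, alpha=alpha, epsilon=epsilon)
        except Exception as exc:  # annotate with the offending measure
            raise type(exc)(f"[measure {m}] {exc}") from exc
        for k in k_grid:
            reports.append(topk_metrics(ls, k, measure=m, seed=seed, fraction=fraction))
    return reports
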