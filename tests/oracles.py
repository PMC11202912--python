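"""Brute-force reference implementations used only as independent oracles.

Each function here deliberately recomputes a quantity by the most direct
method available — exhaustive path enumeration, all-pairs comparison
counting, explicit precision–recall steps — independent of the code paths
they are used to check.
"""

from __future__ import annotations

import itertools
from collections import deque


def bfs_distances(adj: dict, s) -> dict:
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s-t paths by backward DFS over the BFS distance field."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths: list[list] = []

    def back(node, suffix):
        if node == s:
            paths.append([s] + suffix)
            return
        for pred in adj[node]:
            if dist.get(pred, -1) == dist[node] - 1:
                back(pred, [node] + suffix)

    back(t, [])
    return paths


def brute_betweenness(G) -> dict:
    """Unnormalized betweenness over unordered pairs via path enumeration."""
    adj = {u: set(G[u]) for u in G}
    B = {v: 0.0 for v in G}
    for s, t in itertools.combinations(list(G), 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                B[v] += 1.0 / sigma
    return B


def brute_auroc(pos: list[float], neg: list[float]) -> float:
    """P(pos > neg) + 0.5 P(pos = neg) by comparing every pos x neg pair."""
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_aupr(labels_in_rank_order: list[bool]) -> float:
    """Average precision by walking the precision-recall steps explicitly."""
    n_pos = sum(labels_in_rank_order)
    tp = 0
    area = 0.0
    prev_recall = 0.0
    for rank, lab in enumerate(labels_in_rank_order, start=1):
        if lab:
            tp += 1
            recall = tp / n_pos
            precision = tp / rank
            area += (recall - prev_recall) * precision
            prev_recall = recall
    return area
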