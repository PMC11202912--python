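# lpsac

Link prediction in undirected, unweighted networks (protein interaction
maps, collaboration graphs, social networks) by **similarity based on
average centrality (SAC)**: a family of common-neighbor indices that only
counts the *structurally important* common neighbors of a candidate pair.

## The statistic

Classical local link predictors score a non-adjacent pair (v, u) by its
common neighborhood, e.g. the common-neighbor count
CN(v,u) = |Γ(v) ∩ Γ(u)|. SAC filters that neighborhood through a
centrality C and its graph average

    A_C(G) = (1/N) Σ_{v ∈ V} C(v),

    SAC_C(v,u) = |{ x ∈ Γ(v) ∩ Γ(u) : C(x) ≥ A_C(G) }|,

so only common neighbors at or above the network's average centrality are
counted (the threshold is inclusive: a node sitting exactly at the average
counts). Four instances are provided — SAC_D (degree), SAC_B
(betweenness), SAC_C (closeness), SAC_CC (clustering coefficient) —
alongside the five classical indices (CN, Jaccard, Adamic–Adar, resource
allocation, preferential attachment) and two centrality-flavoured ones
(CCPA: α·CN + (1−α)·N/D with D the shortest-path length; KNLP: the
eigenvector-centrality sum of the pair over its clustering-coefficient sum
plus ε). Because SAC compares a centrality only against its own mean, it
is invariant to uniform rescalings such as the degree-centrality
denominator.

Evaluation follows the standard edge-holdout protocol: a random 20% of
edges becomes test positives, every pair non-adjacent in the residual
training graph is scored, and the ranking is summarized by AUROC (midrank
Mann–Whitney) and AUPR (average precision), optionally restricted to the
top-k candidates.

## Worked example

The package ships an 8-node, 12-edge toy network (reconstructed from its
published description; `lpsac.fixtures.reconstruct_toy_oracle` re-derives
it uniquely from the printed constraints at test time):

```python
>>> from lpsac import toy_graph, build_sac_context, score_sac, score_cn
>>> G = toy_graph()
>>> ctx = build_sac_context(G, "degree")   # degree centrality + its average
>>> ctx.average.value
0.375
>>> score_cn(G, ("1", "2")).score          # common neighbors: nodes 4 and 7
2.0
>>> score_sac(G, ("1", "2"), ctx).score    # only node 4 (0.625) clears 0.375
1.0
>>> score_sac(G, ("4", "7"), ctx).score    # nodes 1, 2 sit AT the average: both count
2.0
```

Nodes 1 and 2 share the neighbors 4 and 7; node 4's degree centrality
(5/8 = 0.625) is above the graph average 0.375 while node 7's (0.25) is
not, so SAC_D(1,2) = 1. The same machinery is available from the shell:

```sh
$ lpsac toy --emit-edges toy.txt
$ lpsac score --graph toy.txt --measure sac_d --output scores.tsv
$ lpsac evaluate --graph toy.txt --measures cn,sac_d --seed 42 --k 5,all --report report.json
$ lpsac toy --check-table2      # per-cell report against the published table
```

The `--check-table2` report recomputes all 66 published worked-example
cells: 49 reproduce exactly at one-decimal display, 11 are flagged as
errata (printed values inconsistent with *any* graph satisfying the
mutually consistent cells — the package asserts the disagreement rather
than hiding it), and the 6 KNLP cells are unverifiable because the
publication's ε is unstated.

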