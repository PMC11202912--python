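# Methods

## Model

Let G = (V, E) be an undirected, unweighted simple graph with N = |V|
nodes and m = |E| edges, Γ(v) the neighbor set of v and d_v = |Γ(v)|.
Link prediction assigns every non-adjacent pair (v, u) a similarity score;
pairs are ranked and the top of the ranking is read as the most likely
future or missing links.

The SAC family scores a pair by the number of its common neighbors whose
centrality C is at least the graph-average centrality
A_C(G) = Σ_v C(v) / N:

SAC_C(v,u) = |{x ∈ Γ(v) ∩ Γ(u) : C(x) ≥ A_C(G)}|.

The comparison is **inclusive**. This matters in practice, not just in
principle: in the packaged worked example the pair (4,7) has common
neighbors whose degree centrality equals the average exactly, and the
published score counts both. Four centralities instantiate the family:

| measure | centrality C | locality |
|---------|--------------|----------|
| sac_d   | degree d_v / denom, denom ∈ {N, N−1} (default N) | local |
| sac_cc  | clustering coefficient 2K_v / (d_v(d_v−1)), 0 when d_v < 2 | local |
| sac_c   | closeness (reachable-set variant, see below) | global |
| sac_b   | betweenness (Brandes; normalized by default) | global |

Because the threshold compares a centrality with its own mean, any uniform
rescaling of C leaves SAC unchanged; the degree denominator and the
betweenness normalization flag therefore affect only reported centrality
values, never SAC scores. The suite asserts bit-identical SAC_D under both
degree denominators.

Comparison measures: CN, Jaccard, Adamic–Adar (natural logarithm; this is
the base that reproduces the published worked values, e.g. 2/ln 3 ≈ 1.82),
resource allocation, preferential attachment, CCPA
(α·CN + (1−α)·N/D_{v,u}, default α = 0.8, the value consistent with the
published example; the distance term is taken to 0 for disconnected
pairs), and KNLP ((CS_v + CS_u)/(CC_v + CC_u + ε) with CS eigenvector
centrality at unit L2 norm and default ε = 1e−6, a guard whose published
value is unstated).

## Numerical choices

* **Exact thresholding.** The inclusive SAC comparison is decided with
  exact arithmetic where the centrality is rational: for degree,
  C(x) ≥ A_C(G) reduces to the integer test d_x · N ≥ 2m (independent of
  the denominator convention); clustering coefficients are compared as
  exact fractions. Floating-point means can land an epsilon above a score
  that is mathematically equal to them, silently dropping the
  exactly-average nodes the definition must count — e.g. turning every
  SAC_D score of a regular graph into 0 instead of CN. Betweenness and
  closeness thresholds use double precision; exact ties at the mean are
  not structurally forced for them.
* **Eigenvector centrality** is computed by power iteration on I + A with
  L2 normalization, uniform start, tol 1e−6 (residual between successive
  iterates) and max_iter 1000. The identity shift leaves eigenvectors
  unchanged while separating +λ_max from −λ_max, so bipartite graphs
  (stars, trees) converge; non-convergence raises with the residual.
* **Degree-centrality denominator.** The textbook fraction is
  d_v/(N−1), but the published worked values (0.375 = 3/8, 0.625 = 5/8,
  average 0.375) are all d_v/N. The denominator is an explicit parameter
  defaulting to N so the worked-example surface reproduces exactly; SAC is
  invariant either way.
* **Closeness on disconnected graphs** uses the reachable-set variant
  (R_v−1)/Σ D_{v,u} · (R_v−1)/(N−1), which equals the classical
  (N−1)/Σ D on connected graphs and degrades gracefully otherwise;
  isolated nodes score 0. Clustering of degree-0/1 nodes is defined as 0
  (the formula is 0/0 there).
* **Tie-breaking.** Rankings sort by descending score, then canonical
  pair order (numeric-aware lexicographic on labels), so every ranking,
  split and metric is reproducible across platforms.
* **Display matching.** The published table mixes round-half-away with
  truncation at one decimal (0.667 printed as 0.6, 2.064 printed as 2);
  regression checks accept either rendering, with an epsilon guarding
  binary-float artifacts.

## Evaluation protocol

`split_edges` removes ⌊fraction·m⌋ (≥ 1) edges uniformly at random
(Python `random.Random(seed)` over the canonically sorted edge list;
deterministic per seed). All nodes are kept; the training graph may
disconnect, which is logged, not repaired. Candidates are all pairs
non-adjacent in the training graph; positives are exactly the held-out
edges — the standard protocol when the source experiment does not state
its negative set. One split per seed is shared by all measures so
comparisons are paired.

AUROC uses the midrank (Mann–Whitney) formulation,
P(s_pos > s_neg) + ½P(s_pos = s_neg), identical to the trapezoidal area
under the empirical ROC. AUPR is average precision — Σ precision@rank
over positive ranks divided by n_pos — over the deterministic ranking;
with score ties this depends on the canonical tie order, which is fixed
and documented rather than interpolated. Top-k evaluation restricts the
labeled ranking to its k highest-scored candidates before computing both
metrics; single-class subsets (inevitable at small k) return flagged null
metrics instead of raising. Unrestricted metrics are available by putting
`"all"` in the k-grid.

## The toy fixture and its reconstruction oracle

The worked-example graph exists only as a drawing, so the package ships
the edge set recovered from printed constraints: the PA row forces the
degree sequence (3,3,2,5,4,3,2,2) — each product d_v·d_u factors uniquely
over admissible degrees — the text names {4,7} as the common neighbors of
(1,2), and the six tabulated pairs are non-adjacent.
`reconstruct_toy_oracle` enumerates all graphs meeting those constraints
(depth-first search with degree pruning; runs in milliseconds) and scores
each against the 49 mutually consistent printed cells. The fully
consistent basic rows alone admit a second maximizer, so the objective
spans every consistent cell, under which the packaged graph is the unique
perfect match — with or without the common-neighbor constraint. The 11
erratum cells (CN(5,7); SAC_B(4,8); SAC_C (1,2),(4,7),(4,8); SAC_CC
(4,7),(4,8),(5,7); CCPA (2,3),(4,7),(5,7)) are asserted to *disagree*, so
a change that silently starts matching them fails the suite; the KNLP row
is unverifiable without the published ε and carries no assertion.

## Synthetic data

Property tests and the end-to-end benchmark run on seeded generators
(Erdős–Rényi, Barabási–Albert, planted-partition/stochastic-block), which
emulate the sparsity, degree heterogeneity and community structure that
make common-neighbor indices informative, but not the degree-correlation
and clustering profiles of real interaction networks — so passing tests
demonstrate correctness of the statistics and protocol, not predictive
performance on any real dataset. The end-to-end condition uses four
50-node blocks with p_in = 0.25 and p_out = 0.02: within-community pairs
then expect ≈ 48·0.25² ≈ 3 common neighbors versus ≈ 0 across
communities, the regime where community structure genuinely drives
common-neighbor scores (a substantially sparser choice leaves most
held-out edges with zero common neighbors and no signal for any
neighborhood-based index). At this size all eleven measures evaluate in
seconds on one core; oracle checks use ≤ 12-node graphs where exhaustive
shortest-path enumeration is cheap.

## Limitations

* Directed, weighted and bipartite networks are out of scope; edge lists
  are always read as undirected simple graphs (duplicates and self-loops
  dropped with a log line, or rejected in strict mode).
* Published dataset-level AUROC/AUPR tables are not reproduced here: they
  depend on downloaded data and on negative-sampling/top-k details the
  source does not specify. The harness (`lpsac evaluate`) runs the same
  protocol on any user-supplied edge list.
* KNLP scores depend on an ε whose published value is unknown; defaults
  make the measure well-defined, not comparable to published numbers.
* AUPR with heavy score ties is tie-order dependent by construction; the
  canonical order makes it deterministic but other conventions
  (interpolated PR curves) give different values.
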