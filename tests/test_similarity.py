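import itertools
import math

import networkx as nx
import pytest

from lpsac import (
    SACContext,
    average_centrality,
    build_sac_context,
    degree_centrality,
    non_adjacent_pairs,
    rank_pairs,
    read_edge_list,
    score_aa,
    score_ccpa,
    score_cn,
    score_jc,
    score_knlp,
    score_pa,
    score_ra,
    score_sac,
    table2_report,
)
from lpsac.centrality import CentralityVector
from lpsac.fixtures import TABLE2
from lpsac.graph import canonical_pair


def _simple_scores(G, measure, pair, **kw):
    fn = {
        "cn": score_cn,
        "jc": score_jc,
        "pa": score_pa,
        "ra": score_ra,
        "aa": score_aa,
    }[measure]
    return fn(G, pair, **kw).score


class TestWorkedExamples:
    """Scores on the packaged toy graph against the published worked example."""

    @pytest.mark.parametrize(
        "measure,pair,expected",
        [
            ("cn", ("1", "2"), 2.0),
            ("cn", ("2", "3"), 1.0),
            ("jc", ("1", "2"), 0.5),
            ("jc", ("4", "7"), 0.4),
            ("pa", ("4", "7"), 10.0),
            ("pa", ("1", "2"), 9.0),
            ("ra", ("1", "2"), 1 / 5 + 1 / 2),
            ("ra", ("2", "3"), 1 / 5),
            ("aa", ("4", "7"), 2 / math.log(3)),
            ("aa", ("2", "6"), 1 / math.log(5) + 1 / math.log(4)),
        ],
    )
    def test_classical_indices(self, toy, measure, pair, expected):
        assert _simple_scores(toy, measure, pair) == pytest.approx(expected)

    def test_aa_display_values(self, toy):
        assert round(score_aa(toy, ("4", "7")).score, 4) == 1.8205

    @pytest.mark.parametrize(
        "pair,expected", [(("1", "2"), 2.4), (("2", "6"), 2.4)]
    )
    def test_ccpa_at_published_alpha(self, toy, pair, expected):
        assert score_ccpa(toy, pair, alpha=0.8).score == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kind,pair,expected",
        [
            ("degree", ("1", "2"), 1.0),
            ("degree", ("4", "7"), 2.0),  # both common neighbors sit AT the average
            ("clustering", ("2", "6"), 1.0),
        ],
    )
    def test_sac_examples(self, toy, kind, pair, expected):
        ctx = build_sac_context(toy, kind)
        assert score_sac(toy, pair, ctx).score == expected


class TestPreconditionsAndParams:
    def test_adjacent_pair_rejected_unless_overridden(self, toy):
        with pytest.raises(ValueError, match="adjacent"):
            score_cn(toy, ("1", "4"))
        assert score_cn(toy, ("1", "4"), allow_adjacent=True).score >= 0

    def test_ccpa_alpha_one_reduces_to_cn(self, toy):
        for p in non_adjacent_pairs(toy):
            assert score_ccpa(toy, p, alpha=1.0).score == score_cn(toy, p).score

    def test_ccpa_alpha_out_of_range(self, toy):
        with pytest.raises(ValueError):
            score_ccpa(toy, ("1", "2"), alpha=1.5)

    def test_ccpa_disconnected_pair_drops_distance_term(self):
        G = read_edge_list(["a b", "b c", "x y"])
        assert score_ccpa(G, ("a", "x"), alpha=0.8).score == 0.0

    def test_sac_kind_mismatch_rejected(self, toy):
        cv = degree_centrality(toy)
        from lpsac.centrality import AverageCentrality

        with pytest.raises(ValueError, match="kind"):
            SACContext(cv, AverageCentrality("closeness", 0.375))

    def test_sac_context_checks_stored_average(self, toy):
        from lpsac.centrality import AverageCentrality

        cv = degree_centrality(toy)
        with pytest.raises(ValueError, match="mean"):
            SACContext(cv, AverageCentrality("degree", 0.9))


class TestKnlp:
    @staticmethod
    def _vectors(values_cs, values_cc):
        cs = CentralityVector("eigenvector", values_cs)
        cc = CentralityVector("clustering", values_cc)
        return cs, cc

    def test_zero_clustering_denominator_guard(self):
        G = read_edge_list(["a c", "b c"])
        cs, cc = self._vectors(
            {"a": 0.5, "b": 0.5, "c": 0.1}, {"a": 0.0, "b": 0.0, "c": 0.0}
        )
        assert score_knlp(G, ("a", "b"), cs, cc, epsilon=1e-6).score == pytest.approx(1e6)

    def test_direct_substitution(self):
        G = read_edge_list(["a c", "b c"])
        cs, cc = self._vectors(
            {"a": 0.3, "b": 0.2, "c": 0.1}, {"a": 0.5, "b": 0.5, "c": 0.0}
        )
        assert score_knlp(G, ("a", "b"), cs, cc, epsilon=1e-6).score == pytest.approx(
            0.49999975
        )

    def test_toy_pair_regression_pin(self, toy):
        # Frozen from the dense-eigensolver oracle with hand clustering
        # values CC_1 = 0, CC_2 = 1/3 and epsilon = 1e-6.
        from lpsac.centrality import clustering_coefficient, eigenvector_centrality

        cs = eigenvector_centrality(toy, tol=1e-12, max_iter=100000)
        cc = clustering_coefficient(toy)
        got = score_knlp(toy, ("1", "2"), cs, cc, epsilon=1e-6).score
        assert got == pytest.approx(1.9271405884783284, rel=1e-8)

    def test_epsilon_must_be_positive(self, toy):
        from lpsac.centrality import clustering_coefficient, eigenvector_centrality

        cs = eigenvector_centrality(toy)
        cc = clustering_coefficient(toy)
        with pytest.raises(ValueError):
            score_knlp(toy, ("1", "2"), cs, cc, epsilon=0.0)


class TestRanking:
    def test_sac_d_ranking_over_all_candidates(self, toy):
        ranking = rank_pairs(toy, "sac_d")
        assert len(ranking) == 16
        by_pair = {tuple(sp.pair): sp.score for sp in ranking}
        assert by_pair[("1", "2")] == 1.0

    def test_cn_top_ties_follow_canonical_order(self, toy):
        ranking = rank_pairs(toy, "cn")
        top_score = ranking[0].score
        top = [tuple(sp.pair) for sp in ranking if sp.score == top_score]
        assert top == sorted(top, key=lambda p: (int(p[0]), int(p[1])))

    def test_empty_pair_list_gives_empty_ranking(self, toy):
        assert rank_pairs(toy, "cn", pairs=[]) == []

    def test_unknown_measure_lists_valid_ids(self, toy):
        with pytest.raises(ValueError, match="sac_d"):
            rank_pairs(toy, "katz")

    def test_ranking_is_deterministic(self, toy):
        assert rank_pairs(toy, "ra") == rank_pairs(toy, "ra")


class TestInvariants:
    def test_symmetry_under_pair_orientation(self, random_graphs):
        scorers = ["cn", "jc", "pa", "ra", "aa"]
        for G in random_graphs(10, n=10, p=0.3):
            for p in itertools.islice(non_adjacent_pairs(G), 10):
                for m in scorers:
                    assert _simple_scores(G, m, (p.u, p.v)) == _simple_scores(
                        G, m, (p.v, p.u)
                    )
                assert (
                    score_ccpa(G, (p.u, p.v)).score == score_ccpa(G, (p.v, p.u)).score
                )

    def test_sac_dominated_by_cn_for_all_kinds(self, random_graphs):
        kinds = ("degree", "betweenness", "closeness", "clustering")
        for G in random_graphs(100, n=10, p=0.3, base_seed=9000):
            ctxs = {k: build_sac_context(G, k) for k in kinds}
            for p in non_adjacent_pairs(G):
                cn = score_cn(G, p).score
                for k in kinds:
                    sac = score_sac(G, p, ctxs[k]).score
                    assert 0 <= sac <= cn

    def test_degree_regular_graph_degenerates_to_cn(self):
        cycle = nx.relabel_nodes(nx.cycle_graph(9), str)
        ctx = build_sac_context(cycle, "degree")
        for p in non_adjacent_pairs(cycle):
            assert score_sac(cycle, p, ctx).score == score_cn(cycle, p).score

    def test_sac_invariant_to_degree_denominator(self, toy, random_graphs):
        for G in [toy] + random_graphs(20, n=10, p=0.35):
            ctx_n = build_sac_context(G, "degree", denominator="N")
            ctx_n1 = build_sac_context(G, "degree", denominator="N-1")
            for p in non_adjacent_pairs(G):
                assert score_sac(G, p, ctx_n).score == score_sac(G, p, ctx_n1).score

    def test_ra_and_aa_bounds(self, random_graphs):
        # Common neighbors have degree >= 2, so RA <= CN/2; with max degree
        # below N, each AA term exceeds 1/ln(N).
        for G in random_graphs(20, n=10, p=0.35):
            n = G.number_of_nodes()
            for p in non_adjacent_pairs(G):
                cn = score_cn(G, p).score
                assert score_ra(G, p).score <= cn / 2 + 1e-12
                if max(d for _, d in G.degree()) < n:
                    assert score_aa(G, p).score >= cn / math.log(n) - 1e-12


class TestTable2Regression:
    """Full worked-example table: consistent cells match, errata must not."""

    KNOWN_ERRATA = {
        ("cn", ("5", "7")),
        ("sac_b", ("4", "8")),
        ("sac_c", ("1", "2")),
        ("sac_c", ("4", "7")),
        ("sac_c", ("4", "8")),
        ("sac_cc", ("4", "7")),
        ("sac_cc", ("4", "8")),
        ("sac_cc", ("5", "7")),
        ("ccpa", ("2", "3")),
        ("ccpa", ("4", "7")),
        ("ccpa", ("5", "7")),
    }

    def test_statuses_enumerate_known_errata(self):
        stored = {
            (m, tuple(p))
            for m, row in TABLE2.items()
            for p, (_, status) in row.items()
            if status == "erratum"
        }
        assert stored == self.KNOWN_ERRATA

    def test_consistent_cells_match_and_errata_disagree(self):
        for cell in table2_report():
            key = (cell.measure, tuple(cell.pair))
            if cell.status == "consistent":
                assert cell.match, f"consistent cell {key} no longer reproduced"
            elif cell.status == "erratum":
                assert not cell.match, f"erratum cell {key} unexpectedly matches"
            else:
                assert cell.measure == "knlp"  # unverifiable: no assertion
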