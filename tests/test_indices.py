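from __future__ import annotations

import numpy as np
import pytest

import _oracles as oracle
from ppisim.indices import (
    CLASSIC_INDICES,
    IndexParams,
    ScoreTable,
    classic_score,
    combine_scores,
    jaccard_matrix,
    l3_score,
    lo_score,
    rank_pairs,
    score_index,
    sim_score,
)
from ppisim.network import Network


class TestJaccardMatrix:
    def test_identical_neighborhoods(self):
        # a and c both neighbor exactly {b, d}
        net = Network.from_edges([("a", "b"), ("a", "d"), ("c", "b"), ("c", "d")])
        j = jaccard_matrix(net)
        assert j.loc["a", "c"] == 1.0

    def test_path_example(self, path4):
        j = jaccard_matrix(path4)
        assert j.loc["a", "c"] == 0.5

    def test_disjoint_neighborhoods(self):
        net = Network.from_edges([("a", "b"), ("c", "d")])
        assert jaccard_matrix(net).loc["a", "c"] == 0.0

    def test_diagonal_one_for_positive_degree(self, path4):
        j = jaccard_matrix(path4)
        assert all(j.loc[u, u] == 1.0 for u in path4.nodes)

    def test_rejects_self_loops(self, tmp_path):
        p = tmp_path / "loop.txt"
        p.write_text("a a\na b\n")
        from ppisim.network import read_edge_list

        with pytest.raises(ValueError, match="self-loops"):
            jaccard_matrix(read_edge_list(p))


class TestClassicIndices:
    def test_path_hand_examples(self, path4):
        assert classic_score(path4, "CN").score_of("a", "c") == 1.0
        assert classic_score(path4, "RA").score_of("a", "c") == 0.5
        assert classic_score(path4, "PA").score_of("a", "c") == 2.0  # k_a=1, k_c=2

    def test_no_common_neighbor_scores_zero(self):
        net = Network.from_edges([("a", "b"), ("c", "d")])
        for idx in ("CN", "JC", "AA", "RA"):
            assert classic_score(net, idx).score_of("a", "c") == 0.0

    def test_square_lp_walk_counts(self, square):
        # square a-b-c-d-a: two 2-walks a->c, zero 3-walks
        table = classic_score(square, "LP", IndexParams(beta=0.1))
        assert table.score_of("a", "c") == pytest.approx(2.0)

    @pytest.mark.parametrize("index", ["CN", "JC", "LHN", "AA", "PA", "RA"])
    def test_set_arithmetic_oracle_on_atlas(self, index, atlas_networks):
        fn = oracle.CLASSIC_ORACLES[index]
        for net in atlas_networks[::7]:
            table = classic_score(net, index)
            for (u, v), s in zip(table.pairs, table.scores):
                assert s == pytest.approx(fn(net, u, v), abs=1e-12)

    def test_lp_walk_oracle_on_random_graphs(self, random_networks):
        params = IndexParams(beta=0.05)
        for net in random_networks[:10]:
            table = classic_score(net, "LP", params)
            for (u, v), s in zip(table.pairs, table.scores):
                assert s == pytest.approx(oracle.lp(net, u, v, 0.05), abs=1e-10)

    def test_katz_matches_resolvent(self, random_networks):
        # truncated series vs exact (I - beta*A)^-1 - I; remainder
        # O((beta*lambda)^11) is far below the tolerance at beta=1e-3
        params = IndexParams(beta=1e-3, katz_max_len=10)
        for net in random_networks[:10]:
            m, labels = oracle.katz_closed_form(net, 1e-3)
            idx = {u: i for i, u in enumerate(labels)}
            table = classic_score(net, "Katz", params)
            for (u, v), s in zip(table.pairs, table.scores):
                assert s == pytest.approx(m[idx[u], idx[v]], abs=1e-12)

    def test_katz_divergent_beta_rejected(self, square):
        with pytest.raises(ValueError, match="lambda_max"):
            classic_score(square, "Katz", IndexParams(beta=0.9))

    def test_unknown_index_rejected(self, path4):
        with pytest.raises(ValueError, match="unknown classic index"):
            classic_score(path4, "XX")


class TestL3:
    def test_single_3path_product_normalization(self, path4):
        assert l3_score(path4).score_of("a", "d") == pytest.approx(0.25)

    def test_single_3path_sqrt_normalization(self, path4):
        table = l3_score(path4, IndexParams(l3_normalization="sqrt"))
        assert table.score_of("a", "d") == pytest.approx(0.5)

    def test_no_3path_scores_zero(self, path4):
        assert l3_score(path4).score_of("a", "c") == 0.0

    @pytest.mark.parametrize("norm", ["product", "sqrt"])
    def test_brute_force_oracle_on_atlas(self, norm, atlas_networks):
        params = IndexParams(l3_normalization=norm)
        for net in atlas_networks[::5]:
            table = l3_score(net, params)
            for (u, v), s in zip(table.pairs, table.scores):
                assert s == pytest.approx(
                    oracle.l3_brute(net, u, v, norm), abs=1e-12
                )

    def test_brute_force_oracle_on_random_graphs(self, random_networks):
        for net in random_networks[:15]:
            table = l3_score(net)
            for (u, v), s in zip(table.pairs, table.scores):
                assert s == pytest.approx(oracle.l3_brute(net, u, v), abs=1e-10)

    def test_weighted_edges_enter_numerator(self):
        net = Network.from_edges(
            [("a", "b", 0.5), ("b", "c", 0.8), ("c", "d", 1.0)]
        )
        assert l3_score(net).score_of("a", "d") == pytest.approx(0.5 * 0.8 * 1.0 / 4)

    def test_fresh_3path_increases_score(self, random_networks):
        """Attaching a fresh i–z1–z2–j path (new intermediates) raises L3."""
        for net in random_networks[:5]:
            table = l3_score(net)
            if not table.pairs:
                continue
            (u, v) = table.pairs[0]
            before = table.score_of(u, v)
            grown = net.copy()
            grown.add_edge(u, "zz1")
            grown.add_edge("zz1", "zz2")
            grown.add_edge("zz2", v)
            after = l3_score(grown).score_of(u, v)
            assert after >= before + 0.25 - 1e-12


class TestLO:
    def test_edgeless_graph_scores_zero(self):
        net = Network.from_edges([], nodes=["a", "b", "c"])
        table = lo_score(net)
        assert np.all(table.scores == 0.0)

    def test_path_leading_order_alpha_a3(self, path4):
        s = lo_score(path4, IndexParams(alpha=1e-5)).score_of("a", "d")
        assert s == pytest.approx(1e-5, rel=1e-3)

    def test_matches_4_term_series(self, random_networks):
        """Norm-relative agreement with the truncated odd-power series.

        Entries whose leading walk term is high order carry the series'
        own O(alpha) truncation error, so agreement is asserted on the
        candidate score vector as a whole (relative 2-norm)."""
        params = IndexParams(alpha=1e-5)
        for net in random_networks[:20]:
            series, labels = oracle.lo_series(net, 1e-5, terms=4)
            idx = {u: i for i, u in enumerate(labels)}
            table = lo_score(net, params)
            expect = np.array(
                [series[idx[u], idx[v]] for u, v in table.pairs]
            )
            denom = np.linalg.norm(expect)
            if denom > 0:
                assert np.linalg.norm(table.scores - expect) / denom < 1e-6
            else:
                assert np.all(np.abs(table.scores) < 1e-16)

    def test_symmetric_scores(self, random_networks):
        for net in random_networks[:3]:
            table = lo_score(net)
            for (u, v), s in zip(table.pairs, table.scores):
                assert table.score_of(v, u) == s


class TestSim:
    def test_path_example(self, path4):
        assert sim_score(path4).score_of("a", "d") == pytest.approx(1.0)

    def test_edgeless_graph_scores_zero(self):
        net = Network.from_edges([], nodes=["a", "b", "c"])
        assert np.all(sim_score(net).scores == 0.0)

    @pytest.mark.parametrize("similarity", ["jaccard", "CN", "PA", "RA"])
    def test_summation_form_equals_matrix_form(self, similarity, random_networks):
        """Per-pair neighbor-sum form agrees with AS + SA element-wise."""
        for net in random_networks[:10]:
            table = sim_score(net, similarity)
            for (u, v), s in zip(table.pairs, table.scores):
                assert s == pytest.approx(
                    oracle.sim_sum_form(net, u, v, similarity), abs=1e-9
                )

    def test_summation_form_on_atlas(self, atlas_networks):
        for net in atlas_networks[::11]:
            table = sim_score(net)
            for (u, v), s in zip(table.pairs, table.scores):
                assert s == pytest.approx(
                    oracle.sim_sum_form(net, u, v), abs=1e-12
                )

    def test_variant_names(self, path4):
        assert sim_score(path4, "CN").index_name == "SimCN"
        assert score_index(path4, "SimRA").index_name == "SimRA"


class TestScoreTableInvariants:
    @pytest.mark.parametrize("name", ["Sim", "L3", "LO", "CN", "RA"])
    def test_no_edges_no_self_pairs_sorted(self, name, random_networks):
        for net in random_networks[:5]:
            table = score_index(net, name)
            for u, v in table.pairs:
                assert u < v
                assert not net.has_edge(u, v)
            assert table.pairs == sorted(table.pairs)

    @pytest.mark.parametrize("name", ["Sim", "SimCN", "SimRA", "L3", "CN", "RA", "AA"])
    def test_non_negative_on_unweighted_graphs(self, name, random_networks):
        for net in random_networks[:5]:
            assert np.all(score_index(net, name).scores >= 0)

    def test_new_common_neighbor_never_decreases_2hop_scores(self, random_networks):
        """Adding a fresh common neighbor raises CN/RA/AA monotonically."""
        for net in random_networks[:5]:
            pairs = [p for p in oracle.candidate_pairs(net)][:3]
            for u, v in pairs:
                grown = net.copy()
                grown.add_edge(u, "zfresh")
                grown.add_edge("zfresh", v)
                for idx in ("CN", "RA", "AA"):
                    before = score_index(net, idx).score_of(u, v)
                    after = score_index(grown, idx).score_of(u, v)
                    assert after >= before - 1e-12


class TestCombineAndRank:
    def _table(self, scores: dict) -> ScoreTable:
        pairs = sorted(scores)
        return ScoreTable(
            pairs=pairs,
            scores=np.array([scores[p] for p in pairs], dtype=float),
            index_name="t",
        )

    def test_self_combination_preserves_ranking(self, path4):
        table = sim_score(path4)
        combo = combine_scores([table, table])
        assert [p for p, _ in combo.ranked()] == [p for p, _ in table.ranked()]

    @pytest.mark.parametrize("method", ["minmax_sum", "borda"])
    def test_dominant_pair_stays_top(self, method):
        t1 = self._table({("a", "b"): 5.0, ("a", "c"): 1.0, ("b", "d"): 0.0})
        t2 = self._table({("a", "b"): 9.0, ("a", "c"): 0.0, ("b", "d"): 3.0})
        combo = combine_scores([t1, t2], method=method)
        assert combo.ranked(1)[0][0] == ("a", "b")

    def test_minmax_tie_broken_lexicographically(self):
        t1 = self._table({("a", "p"): 1.0, ("a", "q"): 0.0})
        t2 = self._table({("a", "p"): 0.0, ("a", "q"): 1.0})
        combo = combine_scores([t1, t2])
        assert np.allclose(combo.scores, 1.0)
        assert [p for p, _ in combo.ranked()] == [("a", "p"), ("a", "q")]

    def test_mismatched_universes_rejected(self):
        t1 = self._table({("a", "b"): 1.0})
        t2 = self._table({("a", "c"): 1.0})
        with pytest.raises(ValueError, match="candidate universes"):
            combine_scores([t1, t2])

    def test_constant_table_maps_to_zero(self):
        t1 = self._table({("a", "b"): 3.0, ("a", "c"): 3.0})
        combo = combine_scores([t1, t1])
        assert np.all(combo.scores == 0.0)

    def test_rank_pairs_max_selection(self):
        t = self._table({("a", "b"): 2.0, ("a", "c"): 1.0})
        assert rank_pairs(t, 1) == [(("a", "b"), 2.0)]

    def test_rank_pairs_all_equal_is_lexicographic(self):
        t = self._table({("b", "c"): 1.0, ("a", "d"): 1.0, ("a", "c"): 1.0})
        assert [p for p, _ in rank_pairs(t, 3)] == [
            ("a", "c"),
            ("a", "d"),
            ("b", "c"),
        ]

    def test_rank_pairs_k_beyond_table(self):
        t = self._table({("a", "b"): 1.0})
        assert len(rank_pairs(t, 10)) == 1

    def test_rank_pairs_empty_table_warns(self):
        t = ScoreTable(pairs=[], scores=np.array([]), index_name="t")
        with pytest.warns(UserWarning):
            assert rank_pairs(t, 1) == []

    def test_l3_plus_sim_dispatch(self, path4):
        combo = score_index(path4, "L3+Sim")
        assert combo.index_name == "L3+Sim"
        assert len(combo) == len(sim_score(path4))

    def test_unknown_index_dispatch(self, path4):
        with pytest.raises(ValueError, match="available"):
            score_index(path4, "nope")
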