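from fractions import Fraction
from math import comb

import pandas as pd
import pytest

from convmine.consensus import ConversionDegs
from convmine.evaluate import grn_edge_f1
from convmine.grn import (Grn, TfEnrichment, build_core_network, build_grn,
                          filter_de_tfs, hypergeom_upper_tail, out_degree_ranking,
                          tf_enrichment)
from convmine.io import RegulonDB


def upper_tail_enumeration(k, K, n, N):
    """P(X >= k) by exact counting over all C(N, n) draws."""
    total = comb(N, n)
    hits = sum(comb(K, j) * comb(N - K, n - j)
               for j in range(k, min(K, n) + 1))
    return Fraction(hits, total)


class TestTfEnrichment:
    def test_exhaustive_example(self):
        # N=10, K=4, n=5, overlap=3: 66 favourable draws of 252
        assert upper_tail_enumeration(3, 4, 5, 10) == Fraction(66, 252)
        assert hypergeom_upper_tail(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeom_upper_tail(0, 4, 5, 10) == pytest.approx(1.0)

    def test_degenerate_full_selection(self):
        # regulon ⊆ degs and degs = universe
        assert hypergeom_upper_tail(4, 4, 10, 10) == pytest.approx(1.0)

    def test_enrichment_over_database(self):
        db = RegulonDB(sets={"TFA": frozenset({"G1", "G2", "G3", "G4"}),
                             "TFB": frozenset({"G9", "G10"})},
                       universe=frozenset(f"G{i}" for i in range(1, 11)))
        enr = tf_enrichment({"G1", "G2", "G3", "G5", "G6"}, db, db.universe)
        by_tf = {e.tf: e for e in enr}
        assert by_tf["TFA"].overlap == 3
        assert by_tf["TFA"].p_value == pytest.approx(66 / 252, abs=1e-12)
        assert by_tf["TFB"].overlap == 0
        assert by_tf["TFB"].p_value == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        db = RegulonDB(sets={"TFA": frozenset({"G1"})}, universe=frozenset({"G1"}))
        with pytest.raises(ValueError):
            tf_enrichment({"G1"}, db, frozenset())

    def test_regulon_growth_monotonicity(self):
        # adding a DEG to the regulon never increases p; adding a non-DEG
        # never decreases it
        universe = [f"G{i}" for i in range(1, 11)]
        degs = {"G1", "G2", "G3", "G4"}
        for size in range(1, 8):
            for k in range(0, min(size, len(degs)) + 1):
                p = hypergeom_upper_tail(k, size, len(degs), 10)
                p_deg = hypergeom_upper_tail(k + 1, size + 1, len(degs), 10)
                p_bg = hypergeom_upper_tail(k, size + 1, len(degs), 10)
                assert p_deg <= p + 1e-12
                assert p_bg >= p - 1e-12


class TestDeTfFilter:
    def _degs(self, mapping, fcs):
        s = pd.Series(mapping, dtype=object)
        return ConversionDegs("x", s, pd.Series(fcs))

    def test_p_and_fc_gates(self):
        degs = self._degs({"TFA": "up", "TFB": "up", "TFC": "up"},
                          {"TFA": 1.6, "TFB": 1.2, "TFC": 3.0})
        enr = [TfEnrichment("TFA", 5, 10, 0.03, True),
               TfEnrichment("TFB", 5, 10, 0.03, True),
               TfEnrichment("TFC", 5, 10, 0.20, False)]
        assert filter_de_tfs(enr, degs) == {"TFA": "up"}

    def test_down_regulated_tf_kept_with_direction(self):
        degs = self._degs({"TFA": "down"}, {"TFA": 1 / 1.8})
        enr = [TfEnrichment("TFA", 5, 10, 0.01, True)]
        assert filter_de_tfs(enr, degs) == {"TFA": "down"}

    def test_uncalled_tf_excluded(self):
        degs = self._degs({"TFA": "none"}, {"TFA": 5.0})
        enr = [TfEnrichment("TFA", 5, 10, 0.01, True)]
        assert filter_de_tfs(enr, degs) == {}


class TestGrnConstruction:
    DB = RegulonDB(
        sets={"A": frozenset({"G1", "G2", "G5", "B"}), "B": frozenset({"G1"})},
        universe=frozenset({"G1", "G2", "G5", "G7", "A", "B"}))

    def test_edges_are_regulon_deg_intersection(self):
        g = build_grn({"A": "up"}, {"G1", "G5", "G7"}, self.DB)
        assert g.edges == {("A", "G1"), ("A", "G5")}

    def test_empty_de_tfs(self):
        g = build_grn({}, {"G1"}, self.DB)
        assert g.edges == set() and len(g.nodes) == 0

    def test_self_loop_kept_only_when_tf_is_deg(self):
        db = RegulonDB(sets={"A": frozenset({"A", "G1"})}, universe=frozenset({"A", "G1"}))
        with_loop = build_grn({"A": "up"}, {"A", "G1"}, db)
        without = build_grn({"A": "up"}, {"G1"}, db)
        assert ("A", "A") in with_loop.edges
        assert ("A", "A") not in without.edges

    def test_core_restricted_to_de_tfs(self):
        g = build_core_network({"A": "up", "B": "down"}, self.DB)
        assert g.edges == {("A", "B")}

    def test_core_is_subset_of_grn_when_tfs_are_degs(self):
        de_tfs = {"A": "up", "B": "down"}
        degs = {"A", "B", "G1", "G2"}
        grn = build_grn(de_tfs, degs, self.DB)
        core = build_core_network(de_tfs, self.DB)
        assert core.edges <= grn.edges

    def test_planted_edges_recovered_noiseless(self, small_noiseless_result):
        result, truth, regulon_db = small_noiseless_result
        f1 = grn_edge_f1(result, truth, regulon_db)
        assert all(v == 1.0 for v in f1.values())


class TestOutDegreeRanking:
    def test_counts_and_order(self):
        g = build_grn({"A": "up", "B": "up"},
                      {"G1", "G2"},
                      RegulonDB(sets={"A": frozenset({"G1", "G2"}), "B": frozenset({"G1"})},
                                universe=frozenset({"G1", "G2", "A", "B"})))
        r = out_degree_ranking(g)
        assert r.entries == [("A", 2, 1), ("B", 1, 2)]

    def test_empty(self):
        assert out_degree_ranking(Grn()).entries == []

    def test_ties_share_min_rank_alphabetical(self):
        db = RegulonDB(sets={"X": frozenset({"G1"}), "C": frozenset({"G2"})},
                       universe=frozenset({"G1", "G2", "X", "C"}))
        r = out_degree_ranking(build_grn({"X": "up", "C": "up"}, {"G1", "G2"}, db))
        assert r.entries == [("C", 1, 1), ("X", 1, 1)]

    def test_degree_sum_equals_edge_count(self, small_noiseless_result):
        result, _, _ = small_noiseless_result
        for cg in result.grns.values():
            total = sum(deg for _, deg, _ in out_degree_ranking(cg.grn).entries)
            assert total == len(cg.grn.edges)

    def test_tf_regulating_all_others_tops_core_ranking(self):
        tfs = {"M": "up", "A": "up", "B": "down", "C": "up"}
        db = RegulonDB(sets={"M": frozenset({"A", "B", "C"}), "A": frozenset({"B"}),
                             "B": frozenset({"G9"}), "C": frozenset({"G9"})},
                       universe=frozenset({"A", "B", "C", "M", "G9"}))
        r = out_degree_ranking(build_core_network(tfs, db))
        assert r.entries[0][0] == "M"

    def test_planted_master_in_top5(self, small_noiseless_result):
        result, truth, _ = small_noiseless_result
        for conv, cg in result.grns.items():
            top = set(cg.ranking.top(5))
            assert truth.de_tfs[conv] <= top
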