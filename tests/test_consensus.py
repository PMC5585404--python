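import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from convmine.consensus import (ConversionDegs, DirectionTable, VoteRule,
                                common_signature, cross_species_concordance,
                                merge_conversion, vote)
from convmine.io import RegulonDB


def vote_oracle(calls, rule, fcs=None):
    """Exhaustive counting oracle for `vote`."""
    winners = []
    for d, opp in (("up", "down"), ("down", "up")):
        support = [i for i, c in enumerate(calls) if c == d]
        ok = len(support) >= rule.min_same
        if rule.forbid_opposite and any(c == opp for c in calls):
            ok = False
        if ok and rule.fc_min is not None:
            ok = all(max(fcs[i], 1 / fcs[i]) >= rule.fc_min for i in support)
        if ok:
            winners.append(d)
    return winners[0] if len(winners) == 1 else "none"


def make_table(rows, conversions, fcs=None, genes=None):
    genes = genes or [f"G{i+1}" for i in range(len(rows))]
    ids = list(conversions)
    calls = pd.DataFrame(rows, index=genes, columns=ids)
    fc = pd.DataFrame(fcs, index=genes, columns=ids) if fcs is not None else None
    return DirectionTable(calls=calls, conversions=conversions, fc=fc)


class TestVote:
    def test_eight_of_nine_same_pattern(self):
        calls = ["down"] * 8 + ["none"]
        assert vote(calls, VoteRule(min_same=8)) == "down"

    def test_opposite_call_vetoes_two_of_three(self):
        assert vote(["up", "up", "down"], VoteRule(min_same=2, forbid_opposite=True)) == "none"
        assert vote(["up", "up", "none"], VoteRule(min_same=2, forbid_opposite=True)) == "up"

    def test_all_none(self):
        assert vote(["none"] * 5, VoteRule(min_same=2)) == "none"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vote([], VoteRule(min_same=1))

    def test_fc_gate_on_supporting_datasets(self):
        calls = ["down"] * 3
        assert vote(calls, VoteRule(3, fc_min=1.5), fcs=[0.25, 0.25, 0.25]) == "down"
        assert vote(calls, VoteRule(3, fc_min=1.5), fcs=[0.25, 0.25, 1 / 1.2]) == "none"

    def test_matches_counting_oracle_small(self):
        rules = [VoteRule(2), VoteRule(2, forbid_opposite=True), VoteRule(3),
                 VoteRule(1, forbid_opposite=True)]
        for calls in itertools.product(["up", "down", "none"], repeat=4):
            for rule in rules:
                assert vote(list(calls), rule) == vote_oracle(calls, rule), (calls, rule)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from(["up", "down", "none"]), min_size=1, max_size=8),
           st.integers(1, 8), st.booleans())
    def test_permutation_invariance(self, calls, min_same, forbid):
        rule = VoteRule(min_same=min_same, forbid_opposite=forbid)
        base = vote(calls, rule)
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm = list(rng.permutation(calls))
            assert vote(perm, rule) == base

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from(["up", "down", "none"]), min_size=1, max_size=7),
           st.integers(1, 7))
    def test_agreeing_dataset_never_flips_consensus(self, calls, min_same):
        rule = VoteRule(min_same=min_same, forbid_opposite=True)
        base = vote(calls, rule)
        if base != "none":
            assert vote(calls + [base], rule) == base


class TestMergeConversion:
    def test_single_dataset_passthrough(self):
        t = make_table([["up", "down"], ["none", "up"]], {"d1": "a", "d2": "b"})
        merged = merge_conversion(t, "a", VoteRule(1))
        assert list(merged.direction) == ["up", "none"]

    def test_three_of_four(self):
        t = make_table([["up", "up", "up", "none"]],
                       {f"d{i}": "a" for i in range(4)})
        merged = merge_conversion(t, "a", VoteRule(3, forbid_opposite=True))
        assert merged.direction.iloc[0] == "up"

    def test_unknown_conversion(self):
        t = make_table([["up"]], {"d1": "a"})
        with pytest.raises(KeyError):
            merge_conversion(t, "zzz", VoteRule(1))

    def test_noiseless_merge_equals_planted(self, small_noiseless_result):
        result, truth, _ = small_noiseless_result
        for conv, merged in result.merged.items():
            assert dict(merged.degs) == truth.planted_de(conv)

    def test_representative_fc_is_geometric_mean_of_support(self):
        t = make_table([["up", "up", "none"]], {"d1": "a", "d2": "a", "d3": "a"},
                       fcs=[[2.0, 8.0, 1.0]])
        merged = merge_conversion(t, "a", VoteRule(2))
        assert merged.fc.iloc[0] == pytest.approx(4.0)


class TestCommonSignature:
    def test_strict_tier_gates_on_every_supporting_fc(self):
        fcs = [[0.25] * 8 + [1.0], [0.25] * 7 + [1 / 1.2, 1.0]]
        rows = [["down"] * 8 + ["none"], ["down"] * 8 + ["none"]]
        t = make_table(rows, {f"d{i}": f"c{i}" for i in range(9)}, fcs=fcs)
        full, strict = common_signature(t, VoteRule(8), strict_fc_min=1.5)
        assert ("G1", "down") in full and ("G2", "down") in full
        assert ("G1", "down") in strict and ("G2", "down") not in strict

    def test_seven_of_nine_excluded(self):
        rows = [["down"] * 7 + ["none", "none"]]
        t = make_table(rows, {f"d{i}": f"c{i}" for i in range(9)})
        full, _ = common_signature(t, VoteRule(8), strict_fc_min=None)
        assert full == []

    def test_noiseless_common_equals_planted(self, small_noiseless_result):
        result, truth, _ = small_noiseless_result
        expected = sorted([(g, "up") for g in truth.common_up]
                          + [(g, "down") for g in truth.common_down])
        assert result.common_full == expected
        assert result.common_strict == expected

    def test_needs_two_datasets(self):
        t = make_table([["up"]], {"d1": "a"})
        with pytest.raises(ValueError):
            common_signature(t, VoteRule(1))


class TestCrossSpeciesConcordance:
    def _degs(self, mapping):
        s = pd.Series(mapping, dtype=object)
        return ConversionDegs("x", s, pd.Series(2.0, index=s.index))

    def test_identity_and_inversion(self):
        db = RegulonDB(sets={"TF1": frozenset({"G1", "G2", "G3"})},
                       universe=frozenset({"G1", "G2", "G3"}))
        a = self._degs({"G1": "up", "G2": "down", "G3": "none"})
        b = self._degs({"G1": "down", "G2": "up", "G3": "none"})
        assert cross_species_concordance("TF1", a, a, db) == 1.0
        assert cross_species_concordance("TF1", a, b, db) == 0.0

    def test_no_shared_called_target_flagged(self):
        db = RegulonDB(sets={"TF1": frozenset({"G1"})}, universe=frozenset({"G1"}))
        a = self._degs({"G1": "up"})
        b = self._degs({"G1": "none"})
        assert np.isnan(cross_species_concordance("TF1", a, b, db))

    def test_unknown_tf(self):
        db = RegulonDB(sets={"TF1": frozenset({"G1"})}, universe=frozenset({"G1"}))
        a = self._degs({"G1": "up"})
        with pytest.raises(KeyError):
            cross_species_concordance("NOPE", a, a, db)

    def test_twin_studies_share_planted_directions(self, small_noiseless_study):
        # twin studies: identical planted layout, independent noise draws —
        # like the same conversion profiled in two organisms
        from convmine.io import ExpressionDataset
        from convmine.pipeline import run_analysis
        from convmine.simulate import conversion_map

        cfg, datasets, regulon_db, _, truth = small_noiseless_study

        def with_noise(seed):
            rng = np.random.default_rng(seed)
            noisy = []
            for ds in datasets:
                vals = ds.values * np.exp2(rng.normal(0, 0.5, size=ds.values.shape))
                noisy.append(ExpressionDataset(ds.dataset_id, vals, dict(ds.groups)))
            return run_analysis(noisy, conversion_map(cfg), None, None)

        res_a, res_b = with_noise(101), with_noise(202)
        concordances = []
        for conv, tfs in truth.de_tfs.items():
            for tf in tfs:
                c = cross_species_concordance(tf, res_a.merged[conv], res_b.merged[conv],
                                              regulon_db)
                if not np.isnan(c):
                    concordances.append(c)
        assert concordances and min(concordances) >= 0.9
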