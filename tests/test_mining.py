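import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from virorules import (
    MiningConfig,
    PresenceAbsenceMatrix,
    UndefinedMetricError,
    compute_rule_metrics,
    enumerate_candidate_rules,
    itemset_support,
)
from ._bruteforce import brute_force_rules, frame_to_oracle_dict
from .conftest import make_random_matrix


class TestMetrics:
    @pytest.mark.parametrize(
        "lhs,rhs,expected",
        [
            ([("A", True)], ("B", True), (0.4, 0.8, 2.0)),
            ([("A", False)], ("B", False), (0.5, 1.0, 5 / 3)),
        ],
    )
    def test_toy_matrix_hand_arithmetic(self, toy_matrix, toy_config, lhs, rhs, expected):
        m = compute_rule_metrics(toy_matrix, lhs, rhs, toy_config)
        assert (m.support, m.confidence, m.lift) == pytest.approx(expected, abs=1e-15)

    def test_lift_is_one_under_independence(self, toy_config):
        # P(A)=0.5, P(B)=0.6, P(A and B)=0.3 exactly
        df = pd.DataFrame(
            {"A": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
             "B": [1, 1, 1, 0, 0, 1, 1, 1, 0, 0]},
            index=[f"s{i}" for i in range(10)],
        )
        m = compute_rule_metrics(PresenceAbsenceMatrix(df), [("A", True)], ("B", True),
                                 toy_config)
        assert m.lift == 1.0

    def test_contradictory_itemset_has_zero_support(self, toy_matrix, toy_config):
        assert itemset_support(toy_matrix, [("A", True), ("A", False)], toy_config) == 0.0

    def test_zero_support_sides_raise(self, toy_config):
        df = pd.DataFrame({"A": [1, 1], "B": [0, 0]}, index=["s1", "s2"])
        m = PresenceAbsenceMatrix(df)
        with pytest.raises(UndefinedMetricError):
            compute_rule_metrics(m, [("A", False)], ("B", True), toy_config)

    def test_support_bounded_by_sides(self, toy_matrix, toy_config):
        m = compute_rule_metrics(toy_matrix, [("A", True)], ("B", True), toy_config)
        assert m.support <= m.confidence
        assert m.support <= itemset_support(toy_matrix, [("A", True)], toy_config)
        assert m.support <= itemset_support(toy_matrix, [("B", True)], toy_config)


class TestEnumeration:
    def test_two_virus_matrix_yields_eight_ordered_rules(self, toy_matrix, toy_config):
        rules = enumerate_candidate_rules(toy_matrix, toy_config)
        assert len(rules) == 8
        assert set(rules["rule_form"]) == {"one_to_one"}

    def test_ordered_rules_are_distinct_candidates(self, toy_matrix, toy_config):
        rules = enumerate_candidate_rules(toy_matrix, toy_config)
        keys = {(r["lhs_items"], r["rhs_virus"], r["rhs_state"])
                for _, r in rules.iterrows()}
        assert ((("A", True),), "B", True) in keys
        assert ((("B", True),), "A", True) in keys

    def test_canonical_order_is_deterministic(self, toy_matrix, toy_config):
        r1 = enumerate_candidate_rules(toy_matrix, toy_config)
        r2 = enumerate_candidate_rules(toy_matrix, toy_config)
        pd.testing.assert_frame_equal(r1, r2)

    def test_virus_free_strains_excluded_by_default(self, toy_matrix):
        # strains s6-s10 of the toy matrix carry nothing; default mining
        # estimates probabilities over the 4 infected strains only... s5 has A.
        cfg = MiningConfig(min_support=0.0, min_confidence=0.0)
        sup = itemset_support(toy_matrix, [("A", True)], cfg)
        assert sup == 1.0  # all 5 infected strains carry A

    @pytest.mark.parametrize("max_lhs", [1, 2, 3])
    def test_matches_brute_force_oracle(self, max_lhs):
        rng = np.random.default_rng(100 + max_lhs)
        for _ in range(5):
            n, v = int(rng.integers(10, 40)), int(rng.integers(3, 7))
            matrix = make_random_matrix(rng, n, v)
            ms, mc = float(rng.choice([0.0, 0.1, 0.2])), float(rng.choice([0.0, 0.3]))
            cfg = MiningConfig(max_lhs_size=max_lhs, min_support=ms, min_confidence=mc,
                               include_virus_free_strains=True)
            ours = frame_to_oracle_dict(enumerate_candidate_rules(matrix, cfg))
            oracle = brute_force_rules(matrix.values, matrix.virus_ids, max_lhs, ms, mc)
            assert ours.keys() == oracle.keys()
            for key, truth in oracle.items():
                assert ours[key] == pytest.approx(truth, abs=1e-12, rel=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_support_is_anti_monotone(self, seed):
        rng = np.random.default_rng(seed)
        matrix = make_random_matrix(rng, 30, 5)
        cfg = MiningConfig(min_support=0.0, min_confidence=0.0,
                           include_virus_free_strains=True)
        vids = matrix.virus_ids
        base = [(vids[0], True), (vids[1], False)]
        extended = base + [(vids[2], bool(rng.integers(2)))]
        assert itemset_support(matrix, base, cfg) >= itemset_support(matrix, extended, cfg)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_lift_and_support_are_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        matrix = make_random_matrix(rng, 40, 4)
        cfg = MiningConfig(min_support=0.0, min_confidence=0.0,
                           include_virus_free_strains=True)
        a, b = matrix.virus_ids[:2]
        sa, sb = bool(rng.integers(2)), bool(rng.integers(2))
        try:
            fwd = compute_rule_metrics(matrix, [(a, sa)], (b, sb), cfg)
            rev = compute_rule_metrics(matrix, [(b, sb)], (a, sa), cfg)
        except UndefinedMetricError:
            return
        assert fwd.lift == pytest.approx(rev.lift, rel=1e-12)
        assert fwd.support == rev.support

    def test_deleting_uninvolved_strain_changes_denominator_only(self):
        rng = np.random.default_rng(5)
        matrix = make_random_matrix(rng, 30, 4)
        cfg = MiningConfig(min_support=0.0, min_confidence=0.0,
                           include_virus_free_strains=True)
        a, b = matrix.virus_ids[:2]
        # find a strain satisfying neither A=T nor B=T
        rows = matrix.data
        victim = rows[(rows[a] == 0) & (rows[b] == 0)].index[0]
        n = matrix.n_strains
        before = compute_rule_metrics(matrix, [(a, True)], (b, True), cfg)
        reduced = matrix.subset_strains([s for s in matrix.strain_ids if s != victim])
        after = compute_rule_metrics(reduced, [(a, True)], (b, True), cfg)
        # joint, lhs and rhs counts are unchanged; only n shrinks by one
        assert after.support * (n - 1) == pytest.approx(before.support * n, abs=1e-12)
        assert after.confidence == pytest.approx(before.confidence, rel=1e-12)
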