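"""Apriori mining against a brute-force enumeration oracle and by hand."""

import math

import numpy as np
import pytest

from helpers import brute_force_itemsets, brute_force_rules, random_transactions
from omnirule.apriori import (
    AssociationRule,
    FrequentItemset,
    Transactions,
    filter_by_lift,
    frequent_itemsets,
    generate_rules,
    mine_rules,
    rules_for_item,
)


def _as_dict(itemsets):
    return {fi.items: fi.support for fi in itemsets}


class TestFrequentItemsets:
    def test_toy_supports_match_hand_count(self, toy_transactions):
        got = _as_dict(frequent_itemsets(toy_transactions, 0.5))
        expected = {
            frozenset("A"): 0.75,
            frozenset("B"): 0.75,
            frozenset("C"): 0.75,
            frozenset("AB"): 0.5,
            frozenset("AC"): 0.5,
            frozenset("BC"): 0.5,
        }
        assert got == expected

    def test_min_support_one_yields_nothing_on_toy(self, toy_transactions):
        assert frequent_itemsets(toy_transactions, 1.0) == []

    def test_single_transaction(self):
        tx = Transactions.from_itemsets([{"A"}])
        assert _as_dict(frequent_itemsets(tx, 0.5)) == {frozenset("A"): 1.0}

    def test_empty_transactions_raise(self):
        with pytest.raises(ValueError, match="empty"):
            frequent_itemsets(Transactions.from_itemsets([]), 0.5)
        with pytest.raises(ValueError, match="empty"):
            frequent_itemsets(Transactions.from_itemsets([set(), set()]), 0.5)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_min_support_raises(self, toy_transactions, bad):
        with pytest.raises(ValueError, match="min_support"):
            frequent_itemsets(toy_transactions, bad)

    def test_max_len_caps_cardinality(self, toy_transactions):
        got = frequent_itemsets(toy_transactions, 0.25, max_len=1)
        assert all(len(fi.items) == 1 for fi in got)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        """Complete, exact equivalence with full enumeration on random baskets."""
        rng = np.random.default_rng(seed)
        tx = random_transactions(rng)
        min_support = float(rng.choice([0.1, 0.2, 0.3, 0.4, 0.5]))
        got = _as_dict(frequent_itemsets(tx, min_support))
        expected = brute_force_itemsets(tx, min_support)
        assert got.keys() == expected.keys()
        for k in expected:
            assert got[k] == pytest.approx(expected[k], abs=1e-12)

    def test_downward_closure_on_random_baskets(self):
        rng = np.random.default_rng(99)
        tx = random_transactions(rng)
        got = _as_dict(frequent_itemsets(tx, 0.2))
        for items in got:
            for drop in items:
                if len(items) > 1:
                    assert items - {drop} in got

    def test_monotone_in_min_support(self):
        rng = np.random.default_rng(5)
        tx = random_transactions(rng)
        low = set(_as_dict(frequent_itemsets(tx, 0.1)))
        high = set(_as_dict(frequent_itemsets(tx, 0.3)))
        assert high <= low


class TestRules:
    def test_toy_rule_a_to_b_arithmetic(self, toy_transactions):
        """A->B: confidence 2/3, lift (2/3)/(3/4) = 8/9 -- removed by lift > 1."""
        itemsets = frequent_itemsets(toy_transactions, 0.5)
        rules = generate_rules(itemsets, toy_transactions, min_confidence=0.1)
        ab = [r for r in rules
              if r.antecedent == {"A"} and r.consequent == {"B"}]
        assert len(ab) == 1
        assert ab[0].confidence == pytest.approx(2 / 3, abs=1e-12)
        assert ab[0].lift == pytest.approx(8 / 9, abs=1e-12)
        assert ab[0] not in filter_by_lift(rules, 1.0)

    def test_confidence_one_when_antecedent_implies_consequent(self):
        tx = Transactions.from_itemsets([{"A", "B"}, {"A", "B"}, {"C"}])
        rules = generate_rules(frequent_itemsets(tx, 0.1), tx, 0.1)
        ab = [r for r in rules
              if r.antecedent == {"A"} and r.consequent == {"B"}][0]
        assert ab.confidence == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_rule_metrics_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tx = random_transactions(rng)
        min_support = float(rng.choice([0.1, 0.2, 0.3]))
        min_conf = float(rng.choice([0.3, 0.5, 0.7]))
        rules = generate_rules(
            frequent_itemsets(tx, min_support), tx, min_conf
        )
        expected = brute_force_rules(tx, min_support, min_conf)
        got = {(r.antecedent, r.consequent): (r.support, r.confidence, r.lift)
               for r in rules}
        assert got.keys() == expected.keys()
        for k, (s, c, l) in expected.items():
            gs, gc, gl = got[k]
            assert gs == pytest.approx(s, abs=1e-12)
            assert gc == pytest.approx(c, abs=1e-12)
            assert gl == pytest.approx(l, abs=1e-12)

    def test_metric_identities_hold_on_every_rule(self):
        rng = np.random.default_rng(42)
        tx = random_transactions(rng)
        rules = generate_rules(frequent_itemsets(tx, 0.1), tx, 0.1)
        n = len(tx)
        supp = lambda s: sum(1 for t in tx if s <= t) / n
        singletons = {}
        for r in rules:
            assert 0 < r.support <= r.confidence <= 1 + 1e-12
            assert r.lift > 0
            assert r.lift * supp(r.consequent) == pytest.approx(
                r.confidence, abs=1e-12
            )
            assert r.support == pytest.approx(
                r.lift * supp(r.antecedent) * supp(r.consequent), abs=1e-12
            )
            if len(r.antecedent) == 1 and len(r.consequent) == 1:
                singletons[(r.antecedent, r.consequent)] = r.lift
        for (a, c), lift in singletons.items():
            if (c, a) in singletons:
                assert singletons[(c, a)] == pytest.approx(lift, abs=1e-12)

    def test_monotone_in_min_confidence(self, toy_transactions):
        itemsets = frequent_itemsets(toy_transactions, 0.25)
        loose = generate_rules(itemsets, toy_transactions, 0.1)
        tight = generate_rules(itemsets, toy_transactions, 0.8)
        key = lambda r: (r.antecedent, r.consequent)
        assert {key(r) for r in tight} <= {key(r) for r in loose}

    def test_inconsistent_itemset_support_raises(self, toy_transactions):
        bogus = [FrequentItemset(frozenset("A"), 0.9)]
        with pytest.raises(ValueError, match="inconsistent"):
            generate_rules(bogus, toy_transactions, 0.5)

    def test_disjointness_enforced_by_type(self):
        with pytest.raises(ValueError, match="disjoint"):
            AssociationRule(frozenset("A"), frozenset("A"), 0.5, 0.5, 1.0)


class TestFilterAndQuery:
    def _rules(self):
        mk = lambda a, c, lift: AssociationRule(
            frozenset([a]), frozenset([c]), 0.5, 0.5, lift
        )
        return [mk("A", "B", 0.889), mk("B", "C", 1.0), mk("C", "A", 1.7)]

    def test_lift_exactly_one_is_dropped(self):
        kept = filter_by_lift(self._rules(), 1.0)
        assert [r.lift for r in kept] == [1.7]

    def test_min_lift_zero_keeps_everything_in_order(self):
        rules = self._rules()
        assert filter_by_lift(rules, 0.0) == rules

    def test_rules_for_item_sides(self):
        rules = self._rules()
        assert rules_for_item(rules, "A", "antecedent") == [rules[0]]
        assert rules_for_item(rules, "A", "consequent") == [rules[2]]
        either = rules_for_item(rules, "A", "either")
        assert either == [rules[0], rules[2]]
        assert rules_for_item(rules, "Z", "either") == []
        with pytest.raises(ValueError, match="side"):
            rules_for_item(rules, "A", "both")


class TestTransactionsIO:
    def test_basket_round_trip(self, tmp_path, toy_transactions):
        p = tmp_path / "t.basket"
        toy_transactions.write_basket(p)
        back = Transactions.read_basket(p)
        assert back.itemsets == toy_transactions.itemsets
        assert back.sample_ids == toy_transactions.sample_ids

    def test_incidence_round_trip(self, toy_transactions):
        back = Transactions.from_incidence(toy_transactions.to_incidence())
        assert back.itemsets == toy_transactions.itemsets

    def test_mine_rules_composes_stages(self, toy_transactions):
        rules = mine_rules(toy_transactions, 0.25, 0.1, min_lift=0.0)
        assert all(r.lift > 0 for r in rules)
        # ordering: lift desc, then support desc, then lexicographic
        lifts = [r.lift for r in rules]
        assert lifts == sorted(lifts, reverse=True)
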