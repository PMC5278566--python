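"""Apriori mining, rule screening, exact-ratio algebra, and formatting."""

from fractions import Fraction

import numpy as np
import pytest

from bioprospect import (
    AA_ITEM,
    MiningParams,
    brute_force_rules,
    format_rule_table,
    generate_rules,
    mine_frequent_itemsets,
)
from bioprospect.rule_mining import format_pct, round_half_up
from bioprospect.transactions import TransactionSet, item_count


def random_transaction_set(rng, n_items=8, n_trans=30, aa_prob=0.4):
    items = [f"i{k}" for k in range(n_items)]
    transactions = []
    for _ in range(n_trans):
        t = {i for i in items if rng.random() < 0.3}
        if rng.random() < aa_prob:
            t.add(AA_ITEM)
        transactions.append(frozenset(t))
    return TransactionSet(transactions)


def brute_force_itemsets(ts, min_support, max_len):
    """Independent oracle: enumerate every itemset over the universe."""
    import itertools

    universe = sorted(ts.universe())
    out = []
    for size in range(1, max_len + 1):
        for combo in itertools.combinations(universe, size):
            c = item_count(ts, combo)
            if Fraction(c, ts.n) > Fraction(str(min_support)):
                out.append((frozenset(combo), c))
    return sorted(out, key=lambda kv: (len(kv[0]), tuple(sorted(kv[0]))))


def test_frequent_itemsets_match_exhaustive_enumeration():
    rng = np.random.default_rng(7)
    ts = random_transaction_set(rng, n_trans=50)
    for min_support in (0.02, 0.1, 0.3):
        assert mine_frequent_itemsets(ts, min_support, 3) == brute_force_itemsets(
            ts, min_support, 3
        )


def test_every_subset_of_a_frequent_itemset_is_frequent():
    rng = np.random.default_rng(11)
    ts = random_transaction_set(rng, n_trans=40)
    result = dict(mine_frequent_itemsets(ts, 0.05, 3))
    for itemset in result:
        for item in itemset:
            assert (itemset - {item}) in result or len(itemset) == 1


def test_threshold_is_strict():
    # one transaction in 200 carries the item: support is exactly 0.005
    ts = TransactionSet(
        [frozenset({"rare"})] + [frozenset({"common"})] * 199
    )
    survivors = {s for s, _ in mine_frequent_itemsets(ts, 0.005, 1)}
    assert frozenset({"rare"}) not in survivors
    assert frozenset({"common"}) in survivors


def test_min_support_at_or_above_one_yields_nothing():
    ts = TransactionSet([frozenset({"a"})] * 5)
    assert mine_frequent_itemsets(ts, 1, 2) == []
    with pytest.raises(ValueError):
        mine_frequent_itemsets(ts, 0.1, 0)


def test_universal_item_survives_extreme_threshold():
    ts = TransactionSet(
        [frozenset({"u", f"x{i}"}) for i in range(10)]
    )
    found = mine_frequent_itemsets(ts, Fraction(9, 10), 2)
    assert found == [(frozenset({"u"}), 10)]


def test_apriori_equals_brute_force_on_random_instances():
    rng = np.random.default_rng(2017)
    params_grid = [
        MiningParams(),
        MiningParams(min_support=0.05, min_confidence=0.3, min_lift=1.0),
        MiningParams(min_support=0.0, min_confidence=0.0, min_lift=0.0,
                     max_antecedent_len=3),
    ]
    checked = 0
    for trial in range(200):
        ts = random_transaction_set(
            rng, n_items=int(rng.integers(3, 9)), n_trans=int(rng.integers(5, 40))
        )
        if item_count(ts, {AA_ITEM}) == 0:
            continue
        params = params_grid[trial % len(params_grid)]
        assert generate_rules(ts, params) == brute_force_rules(ts, params)
        checked += 1
    assert checked >= 150


def test_rule_algebra_identities(fixture_ts):
    for rule in generate_rules(fixture_ts):
        assert rule.support * rule.n == rule.n_xy
        assert rule.lift * Fraction(rule.n_y, rule.n) == rule.confidence
        assert rule.support <= rule.confidence
        assert rule.support == rule.confidence * Fraction(rule.n_x, rule.n)


def test_fixture_yields_the_published_bacteria_rule(fixture_ts):
    rules = generate_rules(fixture_ts)
    [bacteria] = [
        r for r in rules if r.antecedent == frozenset({"superkingdom:Bacteria"})
    ]
    assert (bacteria.n_x, bacteria.n_xy, bacteria.n_y, bacteria.n) == (9, 6, 194, 1091)
    formatted = format_rule_table([bacteria])[0]
    assert formatted["support"] == "0.55%"
    assert formatted["confidence"] == "66.67%"
    assert formatted["lift"] == "3.75"


def test_fixture_yields_the_published_double_item_rule(fixture_ts):
    rules = generate_rules(fixture_ts)
    [double] = [
        r
        for r in rules
        if r.antecedent == frozenset({"nature:cold", "kingdom:Viridiplantae"})
    ]
    formatted = format_rule_table([double])[0]
    assert formatted["support"] == "2.57%"
    assert formatted["confidence"] == "56.00%"
    assert formatted["lift"] == "3.15"


def test_certain_rule_has_confidence_one():
    ts = TransactionSet(
        [frozenset({"family:F", AA_ITEM})] * 4 + [frozenset({"g"})] * 16
    )
    [rule] = [
        r for r in generate_rules(ts) if r.antecedent == frozenset({"family:F"})
    ]
    assert rule.confidence == 1
    assert format_rule_table([rule])[0]["confidence"] == "100.00%"


def test_universal_consequent_gives_lift_one_and_is_screened_out():
    ts = TransactionSet([frozenset({"a", AA_ITEM})])
    assert generate_rules(ts) == []
    rules = brute_force_rules(
        ts, MiningParams(min_support=0.0, min_confidence=0.0, min_lift=0.0)
    )
    [rule] = rules
    assert rule.support == rule.confidence == rule.lift == 1


def test_generate_rules_requires_an_aa_transaction():
    ts = TransactionSet([frozenset({"a"})])
    with pytest.raises(ValueError):
        generate_rules(ts)


def test_brute_force_guard_on_large_universe():
    ts = TransactionSet(
        [frozenset({f"i{k}" for k in range(30)} | {AA_ITEM})]
    )
    with pytest.raises(ValueError, match="guard"):
        brute_force_rules(ts)


def test_rounding_is_half_up_at_two_decimals():
    assert str(round_half_up(Fraction(1, 8) * 100)) == "12.50"
    assert format_pct(Fraction(5, 1000)) == "0.50%"
    # exact halves go up, not to even
    assert str(round_half_up(Fraction(25, 1000), 2)) == "0.03"
    assert str(round_half_up(Fraction(125, 1000), 2)) == "0.13"


def test_rule_ordering_is_size_then_confidence_then_name(fixture_ts):
    rules = generate_rules(fixture_ts)
    keys = [
        (len(r.antecedent), -r.confidence, tuple(sorted(r.antecedent)))
        for r in rules
    ]
    assert keys == sorted(keys)
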