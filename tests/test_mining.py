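"""Rule mining: counting oracles, thresholds, confidence policies."""
import pytest
from hypothesis import given, settings, strategies as st

from herbnet._util import pct
from herbnet.datasets import (N_PRESCRIPTIONS, pair_rule_table,
                              published_rules, top_formulas,
                              top_single_herbs)
from herbnet.errors import ConfigurationError, ValidationError
from herbnet.mining import (MiningThresholds, apply_thresholds, build_rules,
                            count_items, count_pairs, mine,
                            reported_confidence, rules_to_frame)
from herbnet.synthetic import generate_prescription_sets

from conftest import brute_force_pair_counts


def test_count_items_is_set_based():
    sets = [frozenset("AB"), frozenset("AB"), frozenset("AC")]
    counts, n_total = count_items(sets)
    assert n_total == 3
    assert counts == {"A": 3, "B": 2, "C": 1}


def test_count_items_validates_against_catalog():
    with pytest.raises(ValidationError, match="ZZ"):
        count_items([frozenset({"A", "ZZ"})], catalog_ids={"A"})


def test_empty_prescription_list():
    counts, n_total = count_items([])
    assert (counts, n_total) == ({}, 0)
    with pytest.raises(ZeroDivisionError):
        pct(1, n_total)


def test_pair_counts_hand_example():
    sets = [frozenset("AB"), frozenset("AB"), frozenset("AC")]
    pair_counts, item_counts, n_total = count_pairs(sets)
    assert pair_counts == {("A", "B"): 2, ("A", "C"): 1}  # BC absent
    assert item_counts == {"A": 3, "B": 2, "C": 1}
    assert n_total == 3


@pytest.mark.parametrize("seed,n", [(3, 1000), (9, 400)])
def test_pair_counts_equal_brute_force(seed, n):
    sets = generate_prescription_sets(n, seed=seed)
    pair_counts, item_counts, _ = count_pairs(sets)
    oracle_pairs, oracle_items = brute_force_pair_counts(sets)
    assert pair_counts == oracle_pairs
    assert item_counts == oracle_items
    # each k-item prescription contributes C(k,2) pair observations
    expected = sum(len(s) * (len(s) - 1) // 2 for s in sets)
    assert sum(pair_counts.values()) == expected


def test_prevalence_formatting_matches_published_tables():
    for frame in (top_formulas(), top_single_herbs()):
        for row in frame.itertuples():
            assert pct(row.n, N_PRESCRIPTIONS) == row.published_pct


def test_published_pair_supports_recompute():
    for row in pair_rule_table().itertuples():
        assert pct(row.n_ab, N_PRESCRIPTIONS) == row.published_support_pct


def test_rank10_confidence_conditions_on_the_rarer_item():
    # 677 coprescriptions; the rarer item is prescribed 2161 times
    assert reported_confidence(677, 15565, 2161, "a", "b") == 677 / 2161
    assert pct(677, 2161) == 31.33


def test_reported_confidence_policies():
    # counts {4, 10}, 2 coprescriptions
    assert reported_confidence(2, 4, 10, "a", "b", "condition_on_rarer") == 0.5
    assert reported_confidence(2, 10, 4, "a", "b", "condition_on_rarer") == 0.5
    assert reported_confidence(2, 10, 4, "a", "b", "condition_on_a") == 0.2
    assert reported_confidence(2, 10, 4, "a", "b", "max_direction") == 0.5
    # n_a = n_b = n_ab -> 100% under any policy
    for policy in ("condition_on_rarer", "condition_on_a", "max_direction"):
        assert reported_confidence(5, 5, 5, "a", "b", policy) == 1.0
    with pytest.raises(ValidationError, match="zero denominator"):
        reported_confidence(0, 0, 4, "a", "b", "condition_on_a")
    with pytest.raises(ConfigurationError, match="policy"):
        reported_confidence(1, 2, 3, "a", "b", "nonsense")


def test_thresholds_drop_and_retain():
    rules = build_rules({("A", "B"): 4, ("A", "C"): 20, ("B", "C"): 40},
                        {"A": 100, "B": 69, "C": 1000}, 1000)
    retained = apply_thresholds(rules, MiningThresholds())
    kept = {r.pair for r in retained}
    assert ("A", "B") not in kept   # support 0.004 < 0.5%
    assert ("A", "C") not in kept   # support 2% but confidence 20/100 < 30%
    assert kept == {("B", "C")}     # support 4%, confidence 40/69 = 58%


def test_threshold_boundary_is_inclusive():
    rules = build_rules({("A", "B"): 5}, {"A": 10, "B": 20}, 1000)
    assert apply_thresholds(rules, MiningThresholds(0.005, 0.5)) == rules


def test_published_rules_all_pass_default_thresholds():
    import dataclasses

    rules = published_rules()
    # with the confidences as printed, every one of the ten published rows
    # clears both default thresholds (weakest: support 1.82%, conf 31.33%)
    printed = dict(zip((tuple(sorted((r.item_a, r.item_b)))
                        for r in pair_rule_table().itertuples()),
                       pair_rule_table()["published_conf_pct"]))
    as_printed = [dataclasses.replace(r, reported_confidence=printed[r.pair] / 100)
                  for r in rules]
    assert len(apply_thresholds(as_printed, MiningThresholds())) == 10
    # recomputing confidence from the published item counts instead, the two
    # rows whose printed denominators match no published count fall below
    # 30% — the known internal inconsistency of the source tables
    retained = apply_thresholds(rules, MiningThresholds())
    assert len(retained) == 8
    frame = rules_to_frame(retained)
    assert frame.loc[0, "item_a"] == "Hedyotis diffusa"
    assert frame.loc[0, "support_pct"] == 10.88
    assert frame.iloc[-1]["support_pct"] == 1.82
    assert frame.iloc[-1]["reported_conf_pct"] == 31.33
    # duplex flag: exactly half of the ten published combinations join two
    # SHs; the duplex flag itself comes from the catalog kinds
    assert sum(r.is_duplex for r in rules) == 5


def test_raising_thresholds_never_adds_rules():
    sets = generate_prescription_sets(2000, seed=12)
    base = {r.pair for r in mine(sets)}
    for thr in (MiningThresholds(0.02, 0.30), MiningThresholds(0.005, 0.5),
                MiningThresholds(0.05, 0.6)):
        tighter = {r.pair for r in mine(sets, thresholds=thr)}
        assert tighter <= base


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.sets(st.sampled_from("ABCDEF"), min_size=1, max_size=5),
                min_size=1, max_size=40))
def test_rule_bounds_invariants(prescriptions):
    sets = [frozenset(s) for s in prescriptions]
    pair_counts, item_counts, n_total = count_pairs(sets)
    rules = build_rules(pair_counts, item_counts, n_total)
    seen = set()
    for r in rules:
        assert r.item_a < r.item_b
        assert r.pair not in seen
        seen.add(r.pair)
        assert r.n_ab <= min(r.n_a, r.n_b)
        assert 0 < r.support <= r.reported_confidence <= 1
        assert r.support == r.n_ab / n_total
        assert r.confidence_a_to_b == r.n_ab / r.n_a
        assert r.confidence_b_to_a == r.n_ab / r.n_b


def test_frequent_itemsets_apriori_matches_enumeration():
    from itertools import combinations

    from herbnet.mining import frequent_itemsets

    sets = [frozenset(s) for s in
            ("AB", "AB", "ABC", "BC", "ABC", "AC", "A", "ABCD")]
    got = frequent_itemsets(sets, min_support=0.25, max_size=3)
    # oracle: enumerate every itemset up to size 3 and count by scanning
    items = sorted({i for s in sets for i in s})
    expected = {}
    for k in (1, 2, 3):
        for combo in combinations(items, k):
            c = sum(1 for s in sets if set(combo) <= s)
            if c >= 0.25 * len(sets):
                expected[frozenset(combo)] = c
    assert got == expected
    # monotonicity: a superset is never more frequent than its subsets
    for itemset, c in got.items():
        for item in itemset:
            if len(itemset) > 1:
                assert c <= got[itemset - {item}]


def test_mine_returns_deterministic_ranking():
    sets = generate_prescription_sets(1500, seed=21)
    r1 = mine(sets)
    r2 = mine(list(reversed(sets)))
    assert [r.pair for r in r1] == [r.pair for r in r2]
    supports = [r.support for r in r1]
    assert supports == sorted(supports, reverse=True)
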