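"""Co-localization rule mining and pair filtering."""

from itertools import chain, combinations

import pytest

from ppistack.coloc import (
    AssociationRule,
    RuleDatabase,
    TransactionSet,
    build_transactions,
    filter_pairs,
    frequent_itemsets,
    iterate_until_coverage,
    mine_rules,
    passes_coloc,
    read_rules,
    write_rules,
)
from ppistack.kb import AnnotationStore


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive enumeration of every itemset and rule.
# ---------------------------------------------------------------------------

def oracle_mine(transactions, min_support, min_confidence):
    items = sorted(set(chain.from_iterable(transactions)))
    n = len(transactions)
    supports = {}
    for size in range(1, len(items) + 1):
        for subset in combinations(items, size):
            count = sum(1 for t in transactions if set(subset) <= t)
            if n and count / n >= min_support:
                supports[frozenset(subset)] = count / n
    rules = set()
    for itemset, support in supports.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for antecedent in combinations(sorted(itemset), r):
                antecedent = frozenset(antecedent)
                confidence = support / supports[antecedent]
                if confidence >= min_confidence:
                    rules.add((antecedent, itemset - antecedent, support, confidence))
    return supports, rules


def as_tuples(rules):
    return {(r.antecedent, r.consequent, r.support, r.confidence) for r in rules}


def tx(*itemsets) -> TransactionSet:
    return TransactionSet(transactions=[frozenset(s) for s in itemsets])


# ---------------------------------------------------------------------------
# Transactions
# ---------------------------------------------------------------------------

def make_store(cc_by_id: dict) -> AnnotationStore:
    store = AnnotationStore()
    for accession, cc in cc_by_id.items():
        store.ingest_record({"id": accession, "go_cc": list(cc)})
    return store


def test_transaction_is_union_of_pair_cc_terms():
    store = make_store({"A": {"nucleus"}, "B": {"nucleus", "cytosol"}})
    out = build_transactions([("A", "B")], store)
    assert out.transactions == [frozenset({"nucleus", "cytosol"})]
    assert out.dropped == 0


def test_empty_cc_pairs_dropped_and_counted():
    store = make_store({"A": set(), "B": set(), "C": {"nucleus"}})
    out = build_transactions([("A", "B"), ("A", "C"), ("A", "Z")], store)
    assert len(out) == 1
    assert out.dropped == 2  # empty union + absent protein


def test_three_pair_fixture_matches_hand_enumeration():
    store = make_store(
        {"A": {"n"}, "B": {"n", "c"}, "C": {"m"}, "D": {"c"}}
    )
    out = build_transactions([("A", "B"), ("A", "C"), ("B", "D")], store)
    assert out.transactions == [
        frozenset({"n", "c"}),
        frozenset({"n", "m"}),
        frozenset({"n", "c"}),
    ]


# ---------------------------------------------------------------------------
# Apriori
# ---------------------------------------------------------------------------

def test_worked_example_rules():
    transactions = tx({"A", "B"}, {"A", "B"}, {"A", "C"})
    rules = mine_rules(transactions, min_support=0.6, min_confidence=0.6)
    assert as_tuples(rules) == {
        (frozenset({"B"}), frozenset({"A"}), 2 / 3, 1.0),
        (frozenset({"A"}), frozenset({"B"}), 2 / 3, (2 / 3) / 1.0),
    }
    # determinism: sorted by confidence descending
    assert rules[0].confidence == 1.0


def test_full_support_leaves_no_rules():
    transactions = tx({"A", "B"}, {"A", "B"}, {"A", "C"})
    freq = frequent_itemsets(transactions.transactions, 1.0)
    assert freq == {frozenset({"A"}): 1.0}
    assert mine_rules(transactions, 1.0, 0.6) == []


def test_empty_transactions_yield_no_rules():
    assert mine_rules(tx(), 0.5, 0.5) == []


def test_parameter_validation():
    with pytest.raises(ValueError):
        mine_rules(tx({"A"}), 0.0, 0.5)
    with pytest.raises(ValueError):
        mine_rules(tx({"A"}), 0.5, 1.5)


def test_apriori_equals_exhaustive_enumeration(rng):
    items = list("ABCDEFGHIJ")
    for _ in range(30):
        n_tx = int(rng.integers(1, 31))
        transactions = [
            frozenset(rng.choice(items, size=rng.integers(1, 6), replace=False))
            for _ in range(n_tx)
        ]
        min_support = float(rng.choice([0.1, 0.2, 0.3, 0.5]))
        min_confidence = float(rng.choice([0.5, 0.6, 0.8]))
        supports, oracle_rules = oracle_mine(transactions, min_support, min_confidence)
        assert frequent_itemsets(transactions, min_support) == supports
        mined = mine_rules(TransactionSet(transactions=transactions), min_support, min_confidence)
        assert as_tuples(mined) == oracle_rules


def test_anti_monotonicity(rng):
    items = list("ABCDEFGH")
    transactions = [
        frozenset(rng.choice(items, size=rng.integers(1, 5), replace=False))
        for _ in range(25)
    ]
    freq = frequent_itemsets(transactions, 0.15)
    for itemset in freq:
        for r in range(1, len(itemset)):
            for subset in combinations(itemset, r):
                assert frozenset(subset) in freq
                assert freq[frozenset(subset)] >= freq[itemset]


# ---------------------------------------------------------------------------
# Iterative coverage
# ---------------------------------------------------------------------------

def test_stops_at_first_covering_level():
    transactions = tx({"n", "c"}, {"n", "c"}, {"n", "m"})
    db = iterate_until_coverage(transactions, ["n", "c"], support_schedule=[0.5, 0.1])
    assert db.min_support == 0.5
    assert {"n", "c"} <= db.mentioned_items()


def test_unreachable_component_exhausts_schedule():
    transactions = tx({"n", "c"}, {"n", "c"})
    db = iterate_until_coverage(transactions, ["vacuole"], support_schedule=[0.5, 0.2])
    assert db.min_support == 0.2  # final level returned with a warning


def test_coverage_achieved_only_at_lower_support():
    # {n, m} co-occur in 1 of 4 transactions: covered at 0.25, not at 0.75
    transactions = tx({"n", "c"}, {"n", "c"}, {"n", "c"}, {"n", "m"})
    for level in (0.75, 0.25):
        rules = mine_rules(transactions, level, 0.5)
        mentioned = set().union(*[r.antecedent | r.consequent for r in rules]) if rules else set()
        assert ("m" in mentioned) == (level == 0.25)
    db = iterate_until_coverage(transactions, ["n", "m"], support_schedule=[0.75, 0.25], min_confidence=0.5)
    assert db.min_support == 0.25


def test_schedule_must_descend():
    with pytest.raises(ValueError, match="descending"):
        iterate_until_coverage(tx({"a"}), [], support_schedule=[0.1, 0.5])
    with pytest.raises(ValueError, match="non-empty"):
        iterate_until_coverage(tx({"a"}), [], support_schedule=[])


# ---------------------------------------------------------------------------
# Filter predicate
# ---------------------------------------------------------------------------

def nucleus_cytosol_rule() -> RuleDatabase:
    return RuleDatabase(
        rules=[
            AssociationRule(
                antecedent=frozenset({"nucleus"}),
                consequent=frozenset({"cytosol"}),
                support=0.5,
                confidence=0.9,
            )
        ]
    )


def test_rule_bridges_pair():
    assert passes_coloc({"nucleus"}, {"cytosol"}, nucleus_cytosol_rule())


def test_filter_is_symmetric():
    db = nucleus_cytosol_rule()
    assert passes_coloc({"cytosol"}, {"nucleus"}, db)


def test_nucleus_vs_extracellular_matrix_removed():
    # the canonical removed case: no rule bridges the two compartments
    db = nucleus_cytosol_rule()
    assert not passes_coloc({"nucleus"}, {"extracellular matrix"}, db)


def test_adding_rules_is_monotone(rng):
    compartments = ["n", "c", "m", "e", "g"]
    rules = [
        AssociationRule(
            antecedent=frozenset({a}), consequent=frozenset({b}), support=0.2, confidence=0.7
        )
        for a, b in [("n", "c"), ("c", "m"), ("m", "e")]
    ]
    for _ in range(100):
        cc_a = set(rng.choice(compartments, size=rng.integers(1, 3), replace=False))
        cc_b = set(rng.choice(compartments, size=rng.integers(1, 3), replace=False))
        for k in range(len(rules)):
            before = passes_coloc(cc_a, cc_b, RuleDatabase(rules=rules[:k]))
            after = passes_coloc(cc_a, cc_b, RuleDatabase(rules=rules[: k + 1]))
            assert after >= before


def test_filter_pairs_reports_reasons():
    store = make_store({"A": {"nucleus"}, "B": {"cytosol"}, "C": {"extracellular matrix"}})
    kept, removed = filter_pairs([("A", "B"), ("A", "C"), ("A", "Z")], store, nucleus_cytosol_rule())
    assert kept == [("A", "B")]
    assert {pair for pair, _ in removed} == {("A", "C"), ("A", "Z")}
    reasons = dict(removed)
    assert "rule" in reasons[("A", "C")]
    assert "missing" in reasons[("A", "Z")]


# ---------------------------------------------------------------------------
# Rule file round trip
# ---------------------------------------------------------------------------

def test_rule_file_round_trip(tmp_path):
    db = RuleDatabase(
        rules=[
            AssociationRule(frozenset({"n", "c"}), frozenset({"m"}), 0.25, 0.75),
            AssociationRule(frozenset({"n"}), frozenset({"c"}), 0.5, 1.0),
        ]
    )
    path = tmp_path / "rules.tsv"
    write_rules(db, path)
    loaded = read_rules(path)
    assert as_tuples(loaded.rules) == as_tuples(db.rules)


def test_duplicate_rule_lines_deduplicated(tmp_path):
    path = tmp_path / "rules.tsv"
    path.write_text("n\tc\t0.5\t1\nn\tc\t0.5\t1\n")
    assert len(read_rules(path)) == 1


def test_malformed_line_rejected_with_line_number(tmp_path):
    path = tmp_path / "rules.tsv"
    path.write_text("n\tc\t0.5\t1\nonly-one-column\n")
    with pytest.raises(ValueError, match=":2"):
        read_rules(path)


def test_hand_written_rule_file(tmp_path):
    path = tmp_path / "rules.tsv"
    path.write_text("nucleus|nucleolus\tcytosol\t0.4\t0.8\nmembrane\tcytosol|ribosome\n")
    db = read_rules(path)
    assert db.rules[0].antecedent == {"nucleus", "nucleolus"}
    assert db.rules[0].consequent == {"cytosol"}
    assert db.rules[0].support == 0.4 and db.rules[0].confidence == 0.8
    assert db.rules[1].antecedent == {"membrane"}
    assert db.rules[1].consequent == {"cytosol", "ribosome"}
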