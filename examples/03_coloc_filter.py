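"""Mine co-localization rules and filter predicted pairs.

Known validated interactions give one cellular-component transaction per
pair; Apriori association rules over those transactions then decide which
predicted pairs are physically plausible. A pair whose compartments are
bridged by no rule (classically: one protein nuclear, the other in the
extracellular matrix) is removed.
"""

from ppistack import AnnotationStore, build_transactions, filter_pairs, iterate_until_coverage

store = AnnotationStore()
for accession, cc in {
    "A": ["nucleus"],
    "B": ["nucleus", "cytosol"],
    "C": ["cytosol"],
    "D": ["nucleus"],
    "E": ["extracellular matrix"],
}.items():
    store.ingest_record({"id": accession, "go_cc": cc})

known_validated = [("A", "B"), ("B", "C"), ("A", "C"), ("B", "D")]
transactions = build_transactions(known_validated, store)
rules = iterate_until_coverage(
    transactions, main_components=["nucleus", "cytosol"], min_confidence=0.6
)
print(f"mined {len(rules)} rules at support {rules.min_support}:")
for rule in rules.rules:
    print(
        f"  {'|'.join(sorted(rule.antecedent))} -> {'|'.join(sorted(rule.consequent))}"
        f"  (support {rule.support:.2f}, confidence {rule.confidence:.2f})"
    )

predicted = [("A", "C"), ("D", "C"), ("A", "E")]
kept, removed = filter_pairs(predicted, store, rules)
print(f"\nkept: {kept}")
for pair, reason in removed:
    print(f"removed {pair}: {reason}")
print(
    "\nA-E is removed because no rule connects the nucleus with the\n"
    "extracellular matrix - there is no membrane channel through which a\n"
    "physical interaction could occur."
)
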