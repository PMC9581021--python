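"""Cellular co-localization filtering of predicted interactions.

Association rules over cellular-component (CC) annotations are mined from
known validated interactions with the Apriori algorithm: each known pair
contributes one transaction, the union of both proteins' CC terms. A
predicted pair passes the filter when some rule connects the two proteins'
compartments — one protein's CC terms intersect the antecedent and the
other's the consequent (checked symmetrically, since physical interaction
is). Pairs in compartments with no bridging rule (the canonical example:
one protein in the nucleus, the other in the extracellular matrix) are
removed.

Mining is run over a descending support schedule until the rules mention
every configured "main" cellular component, mirroring the iterative
coverage stop criterion of the original procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .kb import AnnotationStore

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT_SCHEDULE = (0.5, 0.3, 0.2, 0.1, 0.05)
DEFAULT_MIN_CONFIDENCE = 0.6
ITEM_DELIMITER = "|"


@dataclass
class TransactionSet:
    """One CC itemset per known validated interaction."""

    transactions: list[frozenset[str]] = field(default_factory=list)
    dropped: int = 0

    def __len__(self) -> int:
        return len(self.transactions)

    @property
    def items(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t
        return frozenset(out)


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    def sort_key(self) -> tuple:
        return (
            -self.confidence,
            -self.support,
            tuple(sorted(self.antecedent)),
            tuple(sorted(self.consequent)),
        )


@dataclass
class RuleDatabase:
    rules: list[AssociationRule] = field(default_factory=list)
    min_support: Optional[float] = None
    min_confidence: Optional[float] = None

    def __len__(self) -> int:
        return len(self.rules)

    def mentioned_items(self) -> frozenset[str]:
        out: set[str] = set()
        for rule in self.rules:
            out |= rule.antecedent | rule.consequent
        return frozenset(out)


def build_transactions(
    known_pairs: Iterable[tuple[str, str]], store: AnnotationStore
) -> TransactionSet:
    """Union of both proteins' CC terms per pair; unusable pairs dropped.

    A pair is dropped (and counted) when either protein is absent from the
    store or the union of CC terms is empty.
    """
    out = TransactionSet()
    for id_a, id_b in known_pairs:
        rec_a, rec_b = store.get(id_a), store.get(id_b)
        if rec_a is None or rec_b is None:
            out.dropped += 1
            continue
        transaction = frozenset(rec_a.go_cc | rec_b.go_cc)
        if not transaction:
            out.dropped += 1
            continue
        out.transactions.append(transaction)
    if out.dropped:
        logger.info("dropped %d unusable known pairs while building transactions", out.dropped)
    return out


def frequent_itemsets(
    transactions: Sequence[frozenset[str]], min_support: float
) -> dict[frozenset[str], float]:
    """Classic Apriori level-wise frequent-itemset generation.

    Candidate (k+1)-itemsets are joined from frequent k-itemsets and pruned
    by support anti-monotonicity before counting.
    """
    n = len(transactions)
    if n == 0:
        return {}
    counts: dict[frozenset[str], int] = {}
    for t in transactions:
        for item in t:
            key = frozenset((item,))
            counts[key] = counts.get(key, 0) + 1
    frequent = {
        itemset: c / n for itemset, c in counts.items() if c / n >= min_support
    }
    result = dict(frequent)
    k = 1
    while frequent:
        prev = sorted(frequent, key=lambda s: tuple(sorted(s)))
        candidates: set[frozenset[str]] = set()
        for i, a in enumerate(prev):
            for b in prev[i + 1 :]:
                union = a | b
                if len(union) != k + 1:
                    continue
                if all(frozenset(sub) in frequent for sub in combinations(union, k)):
                    candidates.add(union)
        counts = {c: 0 for c in candidates}
        for t in transactions:
            for c in candidates:
                if c <= t:
                    counts[c] += 1
        frequent = {c: cnt / n for c, cnt in counts.items() if cnt / n >= min_support}
        result.update(frequent)
        k += 1
    return result


def mine_rules(
    transactions: TransactionSet, min_support: float, min_confidence: float
) -> list[AssociationRule]:
    """Apriori frequent itemsets followed by rule extraction.

    Every non-trivial bipartition of each frequent itemset of size >= 2
    yields a candidate rule; those meeting ``min_confidence`` are kept,
    sorted by (confidence, support, lexicographic) descending.
    """
    if not 0 < min_support <= 1:
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if not 0 < min_confidence <= 1:
        raise ValueError(f"min_confidence must be in (0, 1], got {min_confidence}")
    freq = frequent_itemsets(transactions.transactions, min_support)
    rules: list[AssociationRule] = []
    for itemset, support in freq.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for antecedent in combinations(sorted(itemset), r):
                antecedent = frozenset(antecedent)
                confidence = support / freq[antecedent]
                if confidence >= min_confidence:
                    rules.append(
                        AssociationRule(
                            antecedent=antecedent,
                            consequent=itemset - antecedent,
                            support=support,
                            confidence=confidence,
                        )
                    )
    rules.sort(key=AssociationRule.sort_key)
    return rules


def iterate_until_coverage(
    transactions: TransactionSet,
    main_components: Iterable[str],
    support_schedule: Sequence[float] = DEFAULT_SUPPORT_SCHEDULE,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> RuleDatabase:
    """Mine at each support level until the rules cover the main components.

    Stops at the first level whose rule set mentions (antecedent or
    consequent) every main component; otherwise returns the final level's
    rules with a coverage warning. Components appearing in zero
    transactions cannot be covered and are excluded from the feasibility
    target up front (with a warning).
    """
    schedule = list(support_schedule)
    if not schedule:
        raise ValueError("support schedule must be non-empty")
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError(f"support schedule must be strictly descending, got {schedule}")
    wanted = set(main_components)
    reachable = wanted & set(transactions.items)
    if reachable != wanted:
        logger.warning(
            "main components absent from all transactions, excluded from coverage: %s",
            sorted(wanted - reachable),
        )
    db = RuleDatabase()
    # with every requested component unreachable there is no satisfiable
    # stop criterion: run the full schedule and warn
    satisfiable = bool(reachable) or not wanted
    for level in schedule:
        rules = mine_rules(transactions, level, min_confidence)
        db = RuleDatabase(rules=rules, min_support=level, min_confidence=min_confidence)
        if satisfiable and reachable <= db.mentioned_items():
            return db
    logger.warning(
        "support schedule exhausted without covering main components %s", sorted(reachable)
    )
    return db


def passes_coloc(
    cc_a: Iterable[str], cc_b: Iterable[str], rules: RuleDatabase
) -> bool:
    """True iff some rule bridges the two compartment sets (symmetric)."""
    set_a, set_b = set(cc_a), set(cc_b)
    for rule in rules.rules:
        if (set_a & rule.antecedent and set_b & rule.consequent) or (
            set_b & rule.antecedent and set_a & rule.consequent
        ):
            return True
    return False


def write_rules(db: RuleDatabase, path: str | Path) -> None:
    """Tab-separated rule file: antecedent, consequent ("|"-joined items),
    optional support and confidence columns."""
    with open(path, "w") as handle:
        for rule in db.rules:
            handle.write(
                "\t".join(
                    (
                        ITEM_DELIMITER.join(sorted(rule.antecedent)),
                        ITEM_DELIMITER.join(sorted(rule.consequent)),
                        f"{rule.support:.10g}",
                        f"{rule.confidence:.10g}",
                    )
                )
                + "\n"
            )


def read_rules(path: str | Path) -> RuleDatabase:
    """Parse a rule file; duplicates deduplicated with a warning,
    malformed lines rejected with their line number."""
    rules: list[AssociationRule] = []
    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 4 tab-separated columns, got {len(parts)}"
                )
            antecedent = frozenset(x for x in parts[0].split(ITEM_DELIMITER) if x)
            consequent = frozenset(x for x in parts[1].split(ITEM_DELIMITER) if x)
            if not antecedent or not consequent:
                raise ValueError(f"{path}:{lineno}: empty antecedent or consequent")
            key = (antecedent, consequent)
            if key in seen:
                logger.warning("%s:%d: duplicate rule skipped", path, lineno)
                continue
            seen.add(key)
            support = float(parts[2]) if len(parts) == 4 else 0.0
            confidence = float(parts[3]) if len(parts) == 4 else 0.0
            rules.append(
                AssociationRule(
                    antecedent=antecedent,
                    consequent=consequent,
                    support=support,
                    confidence=confidence,
                )
            )
    return RuleDatabase(rules=rules)


def filter_pairs(
    pairs: Iterable[tuple[str, str]], store: AnnotationStore, rules: RuleDatabase
) -> tuple[list[tuple[str, str]], list[tuple[tuple[str, str], str]]]:
    """Split predicted pairs into kept and (removed, reason) lists."""
    kept: list[tuple[str, str]] = []
    removed: list[tuple[tuple[str, str], str]] = []
    for pair in pairs:
        rec_a, rec_b = store.get(pair[0]), store.get(pair[1])
        if rec_a is None or rec_b is None:
            removed.append((pair, "annotation missing"))
            continue
        if passes_coloc(rec_a.go_cc, rec_b.go_cc, rules):
            kept.append(pair)
        else:
            removed.append((pair, "no co-localization rule bridges the compartments"))
    return kept, removed
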