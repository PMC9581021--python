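"""Per-pair evidence scores — the base level of the stacked scheme.

Four detection methods produce six numerical features per candidate pair:

* ``seq``      — sequence evidence, from a pluggable scorer (a precomputed
                 pair->score table from an external sequence-based
                 predictor) or a self-contained 3-mer Jaccard fallback;
* ``go_bp``, ``go_mf``, ``go_cc`` — Pekar semantic similarity aggregated
                 over each Gene Ontology branch;
* ``domain``   — Jaccard between the pair's domain cross product (LDP) and
                 the known domain-domain interaction list (LDC):
                 scoreDomain = |LDC ∩ LDP| / |LDC ∪ LDP|;
* ``pathway``  — Jaccard of the two proteins' pathway memberships:
                 scorePathway = |V_A ∩ V_B| / |V_A ∪ V_B|.

Missing annotations score 0 and are flagged, so reports can distinguish
"no evidence" from "evidence against".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

from .kb import AnnotationStore, ProteinRecord
from .ontology import GoDag, pair_go_similarity

logger = logging.getLogger(__name__)

#: Fixed feature column order used everywhere downstream.
FEATURE_COLUMNS = ("seq", "go_bp", "go_mf", "go_cc", "domain", "pathway")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class DomainInteractionSet:
    """Known domain-domain interaction pairs (3DID-like), canonicalized."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def add(self, d1: str, d2: str) -> None:
        self.pairs.add(canonical_pair(d1, d2))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DomainInteractionSet":
        out = cls()
        for d1, d2 in pairs:
            out.add(d1, d2)
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for d1, d2 in sorted(self.pairs):
                handle.write(f"{d1}\t{d2}\n")

    @classmethod
    def load(cls, path: str | Path) -> "DomainInteractionSet":
        out = cls()
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two tab-separated domain ids")
                out.add(*parts)
        return out


@dataclass(frozen=True)
class FeatureVector:
    """The six evidence scores for one candidate pair, plus missing flags."""

    pair: tuple[str, str]
    scores: tuple[float, ...]  # ordered as FEATURE_COLUMNS
    missing_flags: tuple[bool, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_COLUMNS, self.scores))


def domain_score(
    domains_a: Iterable[str],
    domains_b: Iterable[str],
    known: DomainInteractionSet,
    denominator: str = "union",
) -> float:
    """Domain evidence score in [0, 1].

    LDP is the canonicalized unordered cross product of the two proteins'
    domain sets (self-pairs (d, d) arise when both carry d). With the
    default ``denominator="union"`` the score is |LDC∩LDP| / |LDC∪LDP|;
    ``denominator="ldp_only"`` normalizes by |LDP| instead, an escape hatch
    for the plausible intended normalization when the known list is large.
    Both empty -> 0.
    """
    ldp = {canonical_pair(x, y) for x in domains_a for y in domains_b}
    ldc = known.pairs
    inter = len(ldc & ldp)
    if denominator == "union":
        denom = len(ldc | ldp)
    elif denominator == "ldp_only":
        denom = len(ldp)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    return inter / denom if denom else 0.0


def pathway_score(pathways_a: Iterable[str], pathways_b: Iterable[str]) -> float:
    """Jaccard of pathway memberships; 0 when both sets are empty."""
    va, vb = set(pathways_a), set(pathways_b)
    union = va | vb
    return len(va & vb) / len(union) if union else 0.0


def _kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def validate_sequence(sequence: str) -> None:
    for pos, residue in enumerate(sequence):
        if residue not in AMINO_ACIDS:
            raise ValueError(
                f"non-amino-acid character {residue!r} at position {pos}"
            )


def kmer_jaccard_score(seq_a: str, seq_b: str, k: int = 3) -> float:
    """Fallback sequence evidence: Jaccard of k-mer sets (default k=3).

    Returns 0 if either sequence is shorter than k. Rejects characters
    outside the 20-letter amino-acid alphabet, naming the position.
    """
    validate_sequence(seq_a)
    validate_sequence(seq_b)
    if len(seq_a) < k or len(seq_b) < k:
        return 0.0
    ka, kb = _kmers(seq_a, k), _kmers(seq_b, k)
    return len(ka & kb) / len(ka | kb)


class SequenceScoreTable:
    """Pluggable sequence scorer backed by a precomputed pair->score table
    (three-column file: idA, idB, score), e.g. output of an external
    sequence-based predictor. Pairs are unordered. Missing pairs fall back
    to the k-mer Jaccard score."""

    def __init__(self, scores: Optional[Mapping[tuple[str, str], float]] = None, k: int = 3):
        self.scores = {canonical_pair(*p): float(s) for p, s in (scores or {}).items()}
        self.k = k

    @classmethod
    def load(cls, path: str | Path, k: int = 3) -> "SequenceScoreTable":
        scores: dict[tuple[str, str], float] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected idA<TAB>idB<TAB>score")
                scores[canonical_pair(parts[0], parts[1])] = float(parts[2])
        return cls(scores, k=k)

    def __call__(self, id_a: str, id_b: str, seq_a: str, seq_b: str) -> float:
        key = canonical_pair(id_a, id_b)
        if key in self.scores:
            return self.scores[key]
        return kmer_jaccard_score(seq_a, seq_b, k=self.k)


def sequence_score(
    seq_a: str,
    seq_b: str,
    scorer: Optional[Callable[[str, str, str, str], float]] = None,
    id_a: str = "",
    id_b: str = "",
) -> float:
    if scorer is not None:
        return scorer(id_a, id_b, seq_a, seq_b)
    return kmer_jaccard_score(seq_a, seq_b)


def build_feature_vector(
    pair: tuple[str, str],
    store: AnnotationStore,
    dag: GoDag,
    known: DomainInteractionSet,
    scorer: Optional[Callable[[str, str, str, str], float]] = None,
    domain_denominator: str = "union",
) -> FeatureVector:
    """Assemble the six evidence scores for one candidate pair.

    A protein absent from the store degrades to an all-zero vector with
    every missing flag set and a logged warning — never a crash.
    """
    id_a, id_b = pair
    rec_a = store.query_features(id_a)
    rec_b = store.query_features(id_b)
    if rec_a is None or rec_b is None:
        logger.warning("pair (%s, %s): annotation missing, all scores zeroed", id_a, id_b)
        n = len(FEATURE_COLUMNS)
        return FeatureVector(pair=pair, scores=(0.0,) * n, missing_flags=(True,) * n)
    return _vector_from_records(pair, rec_a, rec_b, dag, known, scorer, domain_denominator)


def _vector_from_records(
    pair: tuple[str, str],
    rec_a: ProteinRecord,
    rec_b: ProteinRecord,
    dag: GoDag,
    known: DomainInteractionSet,
    scorer: Optional[Callable[[str, str, str, str], float]],
    domain_denominator: str,
) -> FeatureVector:
    scores = (
        sequence_score(rec_a.sequence, rec_b.sequence, scorer, rec_a.id, rec_b.id),
        pair_go_similarity(dag, rec_a.go_bp, rec_b.go_bp, "BP"),
        pair_go_similarity(dag, rec_a.go_mf, rec_b.go_mf, "MF"),
        pair_go_similarity(dag, rec_a.go_cc, rec_b.go_cc, "CC"),
        domain_score(rec_a.domains, rec_b.domains, known, domain_denominator),
        pathway_score(rec_a.pathways, rec_b.pathways),
    )
    missing = (
        not rec_a.sequence or not rec_b.sequence,
        not rec_a.go_bp or not rec_b.go_bp,
        not rec_a.go_mf or not rec_b.go_mf,
        not rec_a.go_cc or not rec_b.go_cc,
        not rec_a.domains or not rec_b.domains,
        not rec_a.pathways or not rec_b.pathways,
    )
    return FeatureVector(pair=pair, scores=scores, missing_flags=missing)
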