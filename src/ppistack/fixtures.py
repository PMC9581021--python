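"""Deterministic synthetic inputs for every pipeline stage.

The generators build a toy but structurally faithful world: per-branch
ontology DAGs, an annotated proteome, balanced labeled interaction
datasets with planted evidence signal (interacting pairs share GO terms,
pathways, known-interacting domains, and sequence stretches more often
than non-interacting ones), known-interaction lists for rule mining, and
labeled sentence corpora for the literature miner. Everything is a pure
function of (spec, seed), and each generator returns a manifest recording
the planted ground truth so downstream expectations can be computed
without re-reading generator internals.

These fixtures do not try to emulate real GO topology, UniProt field
richness, or published prose — only the statistical structure the
pipeline's rules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import DomainInteractionSet, canonical_pair
from .kb import AnnotationStore
from .ontology import BRANCHES, GoDag

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Evidence channels a planted sharing event can touch.
CHANNELS = ("seq", "go_bp", "go_mf", "go_cc", "domain", "pathway")


@dataclass
class FixtureSpec:
    """Knobs of the synthetic world; defaults give a clearly separable
    planted-signal dataset at desk scale."""

    seed: int = 0
    n_proteins: int = 200
    dag_size: int = 100  # nodes per ontology branch
    n_domains: int = 300
    n_pathways: int = 100
    n_pairs: int = 200  # total, balanced 50/50
    p_pos: float = 0.9  # per-channel sharing probability for positives
    p_neg: float = 0.1  # ... and for negatives
    terms_per_branch: tuple[int, int] = (1, 4)
    domains_per_protein: tuple[int, int] = (1, 3)
    pathways_per_protein: tuple[int, int] = (1, 3)
    sequence_length: tuple[int, int] = (50, 200)
    n_known_domain_pairs: int = 30  # background 3DID-like entries
    # corpus spec: sentences per pair by class
    hits_per_pair: int = 1
    excluded_per_pair: int = 1
    irrelevant_per_pair: int = 2
    sentences_per_doc: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_neg <= 1.0 and 0.0 <= self.p_pos <= 1.0):
            raise ValueError("sharing probabilities must be in [0, 1]")


def generate_go_dag(spec: FixtureSpec, rng: np.random.Generator | None = None) -> GoDag:
    """One rooted DAG per branch; each non-root node gets 1-2 parents among
    earlier nodes, so the graph is acyclic by construction."""
    rng = rng or np.random.default_rng(spec.seed)
    dag = GoDag()
    for branch in BRANCHES:
        terms = [f"GO:{branch}:{i:04d}" for i in range(spec.dag_size)]
        dag.add_root(terms[0], branch)
        for i, term in enumerate(terms[1:], start=1):
            n_parents = 1 if i == 1 else int(rng.integers(1, 3))
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            dag.add_term(term, [terms[p] for p in parents])
    return dag


def _branch_terms(dag: GoDag, branch: str) -> list[str]:
    return sorted(t for t in dag.graph.nodes if dag.branch_of(t) == branch)


def _random_sequence(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ALPHABET), size=length))


def generate_proteins(
    spec: FixtureSpec, dag: GoDag, rng: np.random.Generator | None = None
) -> AnnotationStore:
    """Annotated proteome: random GO terms per branch, domains, pathways
    and a random amino-acid sequence per protein, all from the seeded
    stream."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    store = AnnotationStore()
    branch_pool = {b: _branch_terms(dag, b) for b in BRANCHES}
    # cellular-component usage is Zipf-skewed: a handful of major
    # compartments (nucleus, cytoplasm, membrane, ...) dominate real
    # annotation sets, which is what makes co-localization co-occurrence
    # minable at all
    cc_weights = 1.0 / np.arange(1, len(branch_pool["CC"]) + 1)
    cc_weights /= cc_weights.sum()
    for i in range(spec.n_proteins):
        raw = {
            "id": f"P{i:04d}",
            "sequence": _random_sequence(rng, *spec.sequence_length),
        }
        for branch, key in (("BP", "go_bp"), ("MF", "go_mf"), ("CC", "go_cc")):
            k = int(rng.integers(spec.terms_per_branch[0], spec.terms_per_branch[1] + 1))
            weights = cc_weights if branch == "CC" else None
            raw[key] = list(
                rng.choice(branch_pool[branch], size=k, replace=False, p=weights)
            )
        k = int(rng.integers(spec.domains_per_protein[0], spec.domains_per_protein[1] + 1))
        raw["domains"] = [f"PF{d:04d}" for d in rng.choice(spec.n_domains, size=k, replace=False)]
        k = int(rng.integers(spec.pathways_per_protein[0], spec.pathways_per_protein[1] + 1))
        raw["pathways"] = [f"ko{p:04d}" for p in rng.choice(spec.n_pathways, size=k, replace=False)]
        store.ingest_record(raw, source="fixture")
    return store


@dataclass
class InteractionDataset:
    """Labeled pair list with the planted-evidence manifest."""

    pairs: list[tuple[str, str]]
    labels: list[int]
    known_domains: DomainInteractionSet
    manifest: list[dict] = field(default_factory=list)

    def write_pairs(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for (a, b), label in zip(self.pairs, self.labels):
                handle.write(f"{a}\t{b}\t{label}\n")


def _plant_sharing(
    raw_a: dict, raw_b: dict, channels: dict[str, bool], known: DomainInteractionSet,
    dag_pool: dict[str, list[str]], rng: np.random.Generator,
) -> None:
    for branch, key in (("BP", "go_bp"), ("MF", "go_mf"), ("CC", "go_cc")):
        if channels[key]:
            source = raw_a[key] or [str(rng.choice(dag_pool[branch]))]
            term = str(rng.choice(sorted(source)))
            for raw in (raw_a, raw_b):
                if term not in raw[key]:
                    raw[key] = sorted(set(raw[key]) | {term})
    if channels["pathway"]:
        pathway = str(rng.choice(sorted(raw_a["pathways"]))) if raw_a["pathways"] else "ko9999"
        raw_b["pathways"] = sorted(set(raw_b["pathways"]) | {pathway})
    if channels["domain"] and raw_a["domains"] and raw_b["domains"]:
        known.add(str(rng.choice(sorted(raw_a["domains"]))), str(rng.choice(sorted(raw_b["domains"]))))
    if channels["seq"]:
        seq_a, seq_b = raw_a["sequence"], raw_b["sequence"]
        span = min(20, len(seq_a), len(seq_b))
        if span >= 3:
            start_a = int(rng.integers(0, len(seq_a) - span + 1))
            start_b = int(rng.integers(0, len(seq_b) - span + 1))
            fragment = seq_a[start_a : start_a + span]
            raw_b["sequence"] = seq_b[:start_b] + fragment + seq_b[start_b + span :]


def generate_interaction_dataset(
    spec: FixtureSpec, store: AnnotationStore, dag: GoDag,
    rng: np.random.Generator | None = None,
) -> InteractionDataset:
    """Balanced labeled dataset with per-channel planted sharing.

    Each sampled pair draws an independent Bernoulli per evidence channel
    (probability ``p_pos`` for positives, ``p_neg`` for negatives); a
    success rewires the two proteins to share a GO term / pathway /
    sequence stretch, or injects the pair's domains into the known
    domain-interaction list. Every planted event is recorded in the
    manifest. Updated records are re-ingested into the store.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    accessions = sorted(store.records)
    if not accessions:
        raise ValueError("store is empty")
    known = DomainInteractionSet()
    # background known domain pairs, independent of any planted signal
    all_domains = [f"PF{d:04d}" for d in range(spec.n_domains)]
    for _ in range(spec.n_known_domain_pairs):
        d1, d2 = rng.choice(all_domains, size=2, replace=False)
        known.add(str(d1), str(d2))

    n_pos = spec.n_pairs // 2
    n_neg = spec.n_pairs - n_pos
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    labels: list[int] = []
    manifest: list[dict] = []
    raws = {acc: store.records[acc].to_json() for acc in accessions}

    for label, count, p_share in ((1, n_pos, spec.p_pos), (0, n_neg, spec.p_neg)):
        made = 0
        while made < count:
            a, b = (str(x) for x in rng.choice(accessions, size=2, replace=False))
            pair = canonical_pair(a, b)
            if pair in seen:
                continue
            seen.add(pair)
            channels = {
                "seq": bool(rng.random() < p_share),
                "go_bp": bool(rng.random() < p_share),
                "go_mf": bool(rng.random() < p_share),
                "go_cc": bool(rng.random() < p_share),
                "domain": bool(rng.random() < p_share),
                "pathway": bool(rng.random() < p_share),
            }
            _plant_sharing(
                raws[pair[0]], raws[pair[1]], channels, known,
                {br: _branch_terms(dag, br) for br in BRANCHES}, rng,
            )
            pairs.append(pair)
            labels.append(label)
            manifest.append({"pair": list(pair), "label": label, "planted": channels})
            made += 1

    for acc in accessions:
        store.ingest_record(raws[acc], source="fixture-planted")
    return InteractionDataset(pairs=pairs, labels=labels, known_domains=known, manifest=manifest)


def generate_known_pairs(
    spec: FixtureSpec, store: AnnotationStore, n_pairs: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Known validated interaction list (rule-mining input): random pairs
    of annotated proteins."""
    rng = rng or np.random.default_rng(spec.seed + 3)
    accessions = sorted(store.records)
    out: list[tuple[str, str]] = []
    for _ in range(n_pairs):
        a, b = (str(x) for x in rng.choice(accessions, size=2, replace=False))
        out.append(canonical_pair(a, b))
    return out


# ---------------------------------------------------------------------------
# Labeled corpora for the literature miner
# ---------------------------------------------------------------------------

_HIT_TEMPLATES = (
    "{a} binds {b} in the nuclear complex.",
    "Our assays showed that {a} interacts directly with {b}.",
    "{a} recruits {b} to the membrane during signaling.",
)
_EXCLUDED_TEMPLATES = (
    "{a} increases the expression of {b} in tumor cells.",
    "{a} acts at the promoter of {b} and may bind it indirectly.",
    "Transcription of {b} rises when {a} is present.",
)
_IRRELEVANT_TEMPLATES = (
    "The cohort was profiled over three years.",
    "Samples were stored at low temperature before analysis.",
    "{a} was measured in isolation across replicates.",
)


@dataclass
class CorpusManifest:
    """Sentence-level ground truth: (doc_id, sentence, class) per pair."""

    entries: list[dict] = field(default_factory=list)

    def planted_hits(self, pair: tuple[str, str]) -> list[dict]:
        return [
            e for e in self.entries
            if tuple(e["pair"]) == tuple(pair) and e["class"] == "hit"
        ]


def generate_corpus(
    pairs: list[tuple[str, str]],
    spec: FixtureSpec,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> CorpusManifest:
    """Emit a per-document plain-text corpus with labeled sentences.

    Hit sentences carry both protein mentions plus an interaction term;
    excluded sentences carry both mentions plus a context-exclusion term
    (the expression/regulation false-positive mode); irrelevant sentences
    mention at most one protein. Sentences are packed into documents of
    ``sentences_per_doc`` each.
    """
    rng = rng or np.random.default_rng(spec.seed + 4)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = CorpusManifest()
    sentences: list[tuple[tuple[str, str], str, str]] = []  # (pair, class, text)
    for pair in pairs:
        a, b = pair
        for _ in range(spec.hits_per_pair):
            tpl = _HIT_TEMPLATES[int(rng.integers(len(_HIT_TEMPLATES)))]
            sentences.append((pair, "hit", tpl.format(a=a, b=b)))
        for _ in range(spec.excluded_per_pair):
            tpl = _EXCLUDED_TEMPLATES[int(rng.integers(len(_EXCLUDED_TEMPLATES)))]
            sentences.append((pair, "excluded", tpl.format(a=a, b=b)))
        for _ in range(spec.irrelevant_per_pair):
            tpl = _IRRELEVANT_TEMPLATES[int(rng.integers(len(_IRRELEVANT_TEMPLATES)))]
            sentences.append((pair, "irrelevant", tpl.format(a=a, b=b)))
    order = rng.permutation(len(sentences))
    for doc_index, start in enumerate(range(0, len(sentences), spec.sentences_per_doc)):
        doc_id = f"DOC{doc_index:04d}"
        chunk = [sentences[i] for i in order[start : start + spec.sentences_per_doc]]
        text = " ".join(s for _, _, s in chunk)
        (out_dir / f"{doc_id}.txt").write_text(f"{doc_id}\tbody\n{text}\n")
        for pair, cls, sentence in chunk:
            manifest.entries.append(
                {"doc_id": doc_id, "pair": list(pair), "class": cls, "sentence": sentence}
            )
    return manifest


def corpus_synonyms(pairs: list[tuple[str, str]]) -> dict[str, list[str]]:
    """Identity synonym map (accession is its own bait symbol)."""
    out: dict[str, list[str]] = {}
    for a, b in pairs:
        out.setdefault(a, [a])
        out.setdefault(b, [b])
    return out
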