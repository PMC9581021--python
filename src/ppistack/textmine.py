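"""Sentence-level interaction-evidence mining over article texts.

For a candidate protein pair, every sentence of every supplied document is
screened: a sentence is *evidence* when (i) at least one synonym of each
pair member is mentioned, (ii) no context-exclusion entry fires (terms, or
complete term-sets, marking gene-expression/regulation context rather than
a physical interaction), and (iii) at least one interaction term (bind,
interact, recruit, signal, ...) survives among the sentence's verb/noun
tokens. The per-pair report lists the hit sentences, the interacting words
found, the matched protein mentions and any experimental-method entities,
plus two summary flags (proteins co-mentioned anywhere; interaction
context found).

All lexicons are plain editable text files and are stemmed on load with
the same stemmer applied to sentences, so matching happens in stem space.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .nlp import STOP_WORDS, porter_stem, pos_tag, split_sentences, stem_all, tokenize

logger = logging.getLogger(__name__)

_TAG = re.compile(r"<[^>]+>")
_DISCARD_SECTIONS = ("ref", "references", "ack", "acknowledgments", "fig", "figure")


@dataclass
class DocumentText:
    doc_id: str
    title: str = ""
    abstract: str = ""
    body_paragraphs: list[str] = field(default_factory=list)
    raw_markup: Optional[str] = None


@dataclass(frozen=True)
class ProcessedSentence:
    doc_id: str
    section: str  # abstract | body
    text: str
    tokens: tuple[str, ...]
    stems: tuple[str, ...]
    kept_tokens: tuple[tuple[str, str], ...]  # (stem, POS) for kept verbs/nouns


@dataclass
class Lexicons:
    """Stemmed lexicons driving the evidence rules.

    ``context_exclusion`` entries are either single stems or stem-sets; a
    set only fires when every member occurs in the sentence.
    """

    interaction_terms: frozenset[str]
    context_exclusion: tuple[frozenset[str], ...]
    method_entities: frozenset[str]
    protein_synonyms: dict[str, frozenset[str]]  # accession -> stemmed symbols

    @classmethod
    def from_raw(
        cls,
        interaction_terms: Iterable[str],
        context_exclusion: Iterable[Iterable[str]],
        method_entities: Iterable[str],
        protein_synonyms: dict[str, Iterable[str]],
    ) -> "Lexicons":
        return cls(
            interaction_terms=frozenset(porter_stem(t.lower()) for t in interaction_terms),
            context_exclusion=tuple(
                frozenset(porter_stem(t.lower()) for t in entry) for entry in context_exclusion
            ),
            method_entities=frozenset(porter_stem(t.lower()) for t in method_entities),
            protein_synonyms={
                acc: frozenset(porter_stem(s.lower()) for s in syns)
                for acc, syns in protein_synonyms.items()
            },
        )

    @classmethod
    def load(cls, directory: str | Path) -> "Lexicons":
        """Load editable plain-text lexicon files from a directory.

        ``interaction_terms.txt`` and ``method_entities.txt``: one term per
        line. ``context_exclusion.txt``: one entry per line, term-sets
        comma-joined. ``protein_synonyms.txt``: accession<TAB>comma-joined
        symbols.
        """
        directory = Path(directory)

        def read_lines(name: str) -> list[str]:
            path = directory / name
            if not path.exists():
                return []
            return [
                line.strip()
                for line in path.read_text().splitlines()
                if line.strip() and not line.startswith("#")
            ]

        synonyms: dict[str, list[str]] = {}
        for line in read_lines("protein_synonyms.txt"):
            accession, _, joined = line.partition("\t")
            synonyms[accession.strip()] = [s.strip() for s in joined.split(",") if s.strip()]
        return cls.from_raw(
            interaction_terms=read_lines("interaction_terms.txt"),
            context_exclusion=[
                [t.strip() for t in line.split(",") if t.strip()]
                for line in read_lines("context_exclusion.txt")
            ],
            method_entities=read_lines("method_entities.txt"),
            protein_synonyms=synonyms,
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "interaction_terms.txt").write_text(
            "\n".join(sorted(self.interaction_terms)) + "\n"
        )
        (directory / "context_exclusion.txt").write_text(
            "\n".join(",".join(sorted(e)) for e in self.context_exclusion) + "\n"
        )
        (directory / "method_entities.txt").write_text(
            "\n".join(sorted(self.method_entities)) + "\n"
        )
        (directory / "protein_synonyms.txt").write_text(
            "\n".join(
                f"{acc}\t{','.join(sorted(syns))}"
                for acc, syns in sorted(self.protein_synonyms.items())
            )
            + "\n"
        )


def default_lexicons(protein_synonyms: Optional[dict[str, Iterable[str]]] = None) -> Lexicons:
    """Shipped starter lexicons; users are expected to edit the files."""
    return Lexicons.from_raw(
        interaction_terms=[
            "bind", "binding", "interact", "interaction", "recruit", "signal",
            "signaling", "associate", "complex", "coimmunoprecipitate",
            "colocalize", "heterodimer", "phosphorylate",
        ],
        context_exclusion=[
            ["expression"], ["promoter"], ["transcription"], ["mrna"],
            ["upregulate"], ["downregulate"], ["knockdown"],
            ["gene", "regulation"],
        ],
        method_entities=[
            "coimmunoprecipitation", "two-hybrid", "pulldown", "crosslinking",
            "fret", "immunoprecipitation", "cosedimentation",
        ],
        protein_synonyms=dict(protein_synonyms or {}),
    )


@dataclass(frozen=True)
class SentenceHit:
    doc_id: str
    sentence: str
    interacting_words: tuple[str, ...]
    proteins_matched: tuple[str, ...]
    method_entities: tuple[str, ...]


@dataclass
class EvidenceReport:
    pair: tuple[str, str]
    hits: list[SentenceHit] = field(default_factory=list)
    proteins_co_mentioned: bool = False
    interaction_context_found: bool = False

    def to_json(self) -> dict:
        return {
            "pair": list(self.pair),
            "proteins_co_mentioned": self.proteins_co_mentioned,
            "interaction_context_found": self.interaction_context_found,
            "hits": [
                {
                    "doc_id": h.doc_id,
                    "sentence": h.sentence,
                    "interacting_words": list(h.interacting_words),
                    "proteins_matched": list(h.proteins_matched),
                    "method_entities": list(h.method_entities),
                }
                for h in self.hits
            ],
        }

    def render_text(self) -> str:
        lines = [
            f"pair: {self.pair[0]} - {self.pair[1]}",
            f"proteins co-mentioned: {self.proteins_co_mentioned}",
            f"interaction context found: {self.interaction_context_found}",
            f"evidence sentences: {len(self.hits)}",
        ]
        for h in self.hits:
            lines.append(
                f"  [{h.doc_id}] {h.sentence}\n"
                f"    interacting words: {', '.join(h.interacting_words)}"
                + (
                    f"\n    methods: {', '.join(h.method_entities)}"
                    if h.method_entities
                    else ""
                )
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Cleaning and preprocessing
# ---------------------------------------------------------------------------

def clean_markup(raw: str, doc_id: str = "") -> DocumentText:
    """Strip simplified article markup into a :class:`DocumentText`.

    Recognizes ``<article id=...>``, ``<title>``, ``<abstract>``, ``<body>``
    with ``<p>`` paragraphs; reference/acknowledgment/figure sections are
    discarded. Raises ValueError on unparseable markup (callers skip the
    document with a logged reason).
    """

    def grab(tag: str, text: str) -> str:
        m = re.search(rf"<{tag}[^>]*>(.*?)</{tag}>", text, re.S)
        return m.group(1) if m else ""

    if "<" not in raw:
        return DocumentText(doc_id=doc_id, body_paragraphs=[p for p in raw.split("\n\n") if p.strip()])
    m = re.search(r"<article[^>]*\bid=\"?([\w.\-]+)\"?[^>]*>", raw)
    if m:
        doc_id = m.group(1)
    if not doc_id:
        raise ValueError("markup document without an id")
    for section in _DISCARD_SECTIONS:
        raw = re.sub(rf"<{section}[^>]*>.*?</{section}>", " ", raw, flags=re.S)
    title = _TAG.sub(" ", grab("title", raw)).strip()
    abstract = _TAG.sub(" ", grab("abstract", raw)).strip()
    body = grab("body", raw)
    paragraphs = [
        _TAG.sub(" ", p).strip()
        for p in re.findall(r"<p[^>]*>(.*?)</p>", body, re.S)
    ]
    paragraphs = [re.sub(r"\s+", " ", p) for p in paragraphs if p]
    if not paragraphs and body.strip():
        paragraphs = [re.sub(r"\s+", " ", _TAG.sub(" ", body)).strip()]
    if not (abstract or paragraphs):
        logger.info("document %s has no abstract or body text after cleaning", doc_id)
    return DocumentText(
        doc_id=doc_id,
        title=title,
        abstract=re.sub(r"\s+", " ", abstract),
        body_paragraphs=[p for p in paragraphs if p],
        raw_markup=None,
    )


def preprocess(text: str, doc_id: str = "", section: str = "body") -> list[ProcessedSentence]:
    """Sentence split, tokenize, lowercase, POS-tag, de-stop, stem.

    ``kept_tokens`` are the stems of verbs and nouns surviving stop-word
    removal, with their coarse POS tags.
    """
    out: list[ProcessedSentence] = []
    for sentence in split_sentences(text):
        tokens = tokenize(sentence)
        stems = stem_all(tokens)
        kept = tuple(
            (stem, tag)
            for token, stem in zip(tokens, stems)
            if token not in STOP_WORDS
            for tag in (pos_tag(token),)
            if tag in ("VERB", "NOUN")
        )
        out.append(
            ProcessedSentence(
                doc_id=doc_id,
                section=section,
                text=sentence,
                tokens=tuple(tokens),
                stems=tuple(stems),
                kept_tokens=kept,
            )
        )
    return out


def iter_sentences(doc: DocumentText) -> Iterable[ProcessedSentence]:
    yield from preprocess(doc.abstract, doc.doc_id, "abstract")
    for paragraph in doc.body_paragraphs:
        yield from preprocess(paragraph, doc.doc_id, "body")


# ---------------------------------------------------------------------------
# Evidence rules
# ---------------------------------------------------------------------------

def context_excluded(sentence: ProcessedSentence, lexicons: Lexicons) -> bool:
    """True iff an exclusion term — or every member of an exclusion
    term-set — occurs among the sentence's stems."""
    stems = set(sentence.stems)
    return any(entry <= stems for entry in lexicons.context_exclusion)


def _match_synonyms(stems: set[str], accession: str, lexicons: Lexicons) -> frozenset[str]:
    synonyms = lexicons.protein_synonyms.get(accession, frozenset({porter_stem(accession.lower())}))
    return frozenset(s for s in synonyms if s in stems)


def find_pair_evidence(
    sentence: ProcessedSentence, pair: tuple[str, str], lexicons: Lexicons
) -> Optional[SentenceHit]:
    """A hit needs both proteins mentioned, no exclusion fired, and at
    least one interaction term among the kept verb/noun stems."""
    stems = set(sentence.stems)
    matched_a = _match_synonyms(stems, pair[0], lexicons)
    matched_b = _match_synonyms(stems, pair[1], lexicons)
    if not (matched_a and matched_b):
        return None
    if context_excluded(sentence, lexicons):
        return None
    kept_stems = {stem for stem, _ in sentence.kept_tokens}
    interacting = sorted(kept_stems & lexicons.interaction_terms)
    if not interacting:
        return None
    methods = sorted(stems & lexicons.method_entities)
    return SentenceHit(
        doc_id=sentence.doc_id,
        sentence=sentence.text,
        interacting_words=tuple(interacting),
        proteins_matched=tuple(sorted(matched_a | matched_b)),
        method_entities=tuple(methods),
    )


def evaluate_pair(
    documents: Iterable[DocumentText], pair: tuple[str, str], lexicons: Lexicons
) -> EvidenceReport:
    """Aggregate evidence for one pair over all sentences of all documents."""
    report = EvidenceReport(pair=pair)
    for doc in documents:
        for sentence in iter_sentences(doc):
            stems = set(sentence.stems)
            if _match_synonyms(stems, pair[0], lexicons) and _match_synonyms(
                stems, pair[1], lexicons
            ):
                report.proteins_co_mentioned = True
            hit = find_pair_evidence(sentence, pair, lexicons)
            if hit is not None:
                report.hits.append(hit)
    report.interaction_context_found = bool(report.hits)
    assert not report.interaction_context_found or report.proteins_co_mentioned
    return report


# ---------------------------------------------------------------------------
# Corpus I/O
# ---------------------------------------------------------------------------

def read_corpus(directory: str | Path) -> list[DocumentText]:
    """Load a directory of per-document files.

    ``*.txt``: one-line header ``doc_id<TAB>section`` (abstract|body)
    followed by the cleaned text. ``*.xml``: simplified article markup fed
    through :func:`clean_markup`; unparseable documents are skipped with a
    logged reason.
    """
    directory = Path(directory)
    docs: dict[str, DocumentText] = {}
    for path in sorted(directory.iterdir()):
        if path.suffix == ".txt":
            lines = path.read_text().splitlines()
            if not lines or "\t" not in lines[0]:
                logger.warning("skipping %s: missing doc_id<TAB>section header", path)
                continue
            doc_id, section = lines[0].split("\t", 1)
            text = "\n".join(lines[1:]).strip()
            doc = docs.setdefault(doc_id, DocumentText(doc_id=doc_id))
            if section.strip() == "abstract":
                doc.abstract = (doc.abstract + " " + text).strip()
            else:
                doc.body_paragraphs.append(text)
        elif path.suffix == ".xml":
            try:
                doc = clean_markup(path.read_text())
            except ValueError as exc:
                logger.warning("skipping %s: %s", path, exc)
                continue
            docs[doc.doc_id] = doc
    return [docs[k] for k in sorted(docs)]


def write_report(report: EvidenceReport, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{report.pair[0]}_{report.pair[1]}"
    (directory / f"{stem}.json").write_text(json.dumps(report.to_json(), indent=1))
    (directory / f"{stem}.txt").write_text(report.render_text() + "\n")
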