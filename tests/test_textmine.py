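"""Literature evidence mining: cleaning, preprocessing, evidence rules."""

import numpy as np
import pytest

from ppistack.fixtures import FixtureSpec, corpus_synonyms, generate_corpus
from ppistack.nlp import porter_stem
from ppistack.textmine import (
    Lexicons,
    clean_markup,
    context_excluded,
    default_lexicons,
    evaluate_pair,
    find_pair_evidence,
    preprocess,
    read_corpus,
)


@pytest.fixture
def lexicons() -> Lexicons:
    return default_lexicons(
        {"P1": ["proteina", "pa1"], "P2": ["proteinb"], "P3": ["proteinc"]}
    )


# ---------------------------------------------------------------------------
# Markup cleaning
# ---------------------------------------------------------------------------

def test_simple_paragraph_tag_stripped():
    doc = clean_markup('<article id="D1"><body><p>A binds B.</p></body></article>')
    assert doc.body_paragraphs == ["A binds B."]


def test_references_only_document_has_empty_body():
    doc = clean_markup('<article id="D2"><ref>Smith et al. 2001</ref></article>')
    assert doc.abstract == "" and doc.body_paragraphs == []


def test_nested_tags_match_hand_stripped_expectation():
    raw = (
        '<article id="D3"><title>On <i>binding</i></title>'
        "<abstract>X <b>binds</b> <i>Y</i> strongly.</abstract>"
        "<body><p>First <em>nested <b>deep</b></em> paragraph.</p>"
        "<fig>Figure 1: ignored</fig><p>Second.</p></body></article>"
    )
    doc = clean_markup(raw)
    assert doc.abstract == "X binds Y strongly."
    assert doc.body_paragraphs == ["First nested deep paragraph.", "Second."]


def test_markup_without_id_rejected():
    with pytest.raises(ValueError, match="id"):
        clean_markup("<article><body><p>text</p></body></article>")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def test_kept_stems_include_protein_names_and_verb():
    sentences = preprocess("ProteinA binds ProteinB.")
    assert len(sentences) == 1
    kept = {stem for stem, _ in sentences[0].kept_tokens}
    assert {"proteina", "bind", "proteinb"} <= kept


def test_sentence_splitter_contract():
    assert len(preprocess("It was. Then it bound.")) == 2


def test_preprocessing_is_deterministic():
    text = "ProteinA recruits ProteinB. The complex forms. Nothing else happened."
    assert preprocess(text) == preprocess(text)


def test_five_sentence_paragraph_matches_hand_tagging():
    text = (
        "ProteinA binds ProteinB. "
        "The interaction was strong. "
        "It was not seen before. "
        "Expression of ProteinC increased. "
        "These proteins form a complex."
    )
    sentences = preprocess(text)
    kept = [{stem for stem, _ in s.kept_tokens} for s in sentences]
    assert kept[0] == {"proteina", "bind", "proteinb"}
    assert kept[1] == {"interact", "strong"}  # 'the', 'was' stopped
    assert kept[2] == {"seen"}  # 'it', 'was', 'not', 'before' are stop words
    assert {"express", "proteinc", "increas"} <= kept[3]
    assert {"protein", "form", "complex"} <= kept[4]


# ---------------------------------------------------------------------------
# Context exclusion
# ---------------------------------------------------------------------------

def test_single_exclusion_term_fires(lexicons):
    sentence = preprocess("proteina increases expression of proteinb")[0]
    assert context_excluded(sentence, lexicons)


def test_term_set_requires_all_members():
    lex = Lexicons.from_raw(
        interaction_terms=["bind"],
        context_exclusion=[["promoter", "transcription"]],
        method_entities=[],
        protein_synonyms={},
    )
    only_one = preprocess("the promoter region was active")[0]
    both = preprocess("the promoter drives transcription here")[0]
    assert not context_excluded(only_one, lex)
    assert context_excluded(both, lex)


def test_clean_interaction_sentence_not_excluded(lexicons):
    sentence = preprocess("proteina binds proteinb strongly")[0]
    assert not context_excluded(sentence, lexicons)


# ---------------------------------------------------------------------------
# Pair evidence
# ---------------------------------------------------------------------------

def test_hit_records_interacting_word(lexicons):
    sentence = preprocess("ProteinA binds ProteinB in vitro.", doc_id="D1")[0]
    hit = find_pair_evidence(sentence, ("P1", "P2"), lexicons)
    assert hit is not None
    assert "bind" in hit.interacting_words
    assert set(hit.proteins_matched) == {"proteina", "proteinb"}


def test_single_protein_mention_is_no_hit(lexicons):
    sentence = preprocess("ProteinA binds something else.")[0]
    assert find_pair_evidence(sentence, ("P1", "P2"), lexicons) is None


def test_expression_context_blocks_hit(lexicons):
    # the classic false-positive mode: regulation context, not binding
    sentence = preprocess("ProteinA increases expression of ProteinB.")[0]
    assert context_excluded(sentence, lexicons)
    assert find_pair_evidence(sentence, ("P1", "P2"), lexicons) is None


def test_method_entities_recorded(lexicons):
    sentence = preprocess(
        "Coimmunoprecipitation showed that ProteinA binds ProteinB."
    )[0]
    hit = find_pair_evidence(sentence, ("P1", "P2"), lexicons)
    assert hit is not None and len(hit.method_entities) == 1
    assert hit.method_entities[0] == porter_stem("coimmunoprecipitation")


def test_synonym_matching_uses_any_symbol(lexicons):
    sentence = preprocess("PA1 binds ProteinB.")[0]
    assert find_pair_evidence(sentence, ("P1", "P2"), lexicons) is not None


# ---------------------------------------------------------------------------
# Per-pair aggregation
# ---------------------------------------------------------------------------

def doc_of(text: str, doc_id: str = "D1"):
    from ppistack.textmine import DocumentText

    return DocumentText(doc_id=doc_id, body_paragraphs=[text])


def test_report_lists_hits(lexicons):
    docs = [doc_of("ProteinA binds ProteinB here. Unrelated sentence follows.")]
    report = evaluate_pair(docs, ("P1", "P2"), lexicons)
    assert report.interaction_context_found and report.proteins_co_mentioned
    assert len(report.hits) == 1


def test_excluded_co_mention_sets_flag_only(lexicons):
    docs = [doc_of("ProteinA increases expression of ProteinB.")]
    report = evaluate_pair(docs, ("P1", "P2"), lexicons)
    assert report.proteins_co_mentioned
    assert not report.interaction_context_found and report.hits == []


def test_empty_corpus_reports_nothing(lexicons):
    report = evaluate_pair([], ("P1", "P2"), lexicons)
    assert not report.proteins_co_mentioned and not report.interaction_context_found


def test_determinism_on_identical_corpus(lexicons):
    docs = [doc_of("ProteinA binds ProteinB here.", "D1"), doc_of("Noise.", "D2")]
    r1 = evaluate_pair(docs, ("P1", "P2"), lexicons)
    r2 = evaluate_pair(docs, ("P1", "P2"), lexicons)
    assert r1.to_json() == r2.to_json()


# ---------------------------------------------------------------------------
# Generator-labeled corpora: exact hit recovery
# ---------------------------------------------------------------------------

def test_planted_hits_recovered_exactly(tmp_path):
    spec = FixtureSpec(seed=42, hits_per_pair=3, excluded_per_pair=2, irrelevant_per_pair=2)
    pairs = [("P0001", "P0002"), ("P0003", "P0004"), ("P0005", "P0006")]
    manifest = generate_corpus(pairs, spec, tmp_path / "corpus")
    documents = read_corpus(tmp_path / "corpus")
    lexicons = default_lexicons(corpus_synonyms(pairs))
    for pair in pairs:
        planted = manifest.planted_hits(pair)
        report = evaluate_pair(documents, pair, lexicons)
        found = {(h.doc_id, h.sentence) for h in report.hits}
        expected = {(e["doc_id"], e["sentence"]) for e in planted}
        assert found == expected  # precision and recall both 1.0
        assert report.interaction_context_found


def test_zero_planted_hits_means_no_context(tmp_path):
    spec = FixtureSpec(seed=7, hits_per_pair=0, excluded_per_pair=2, irrelevant_per_pair=3)
    pairs = [("P0001", "P0002")]
    generate_corpus(pairs, spec, tmp_path / "corpus")
    documents = read_corpus(tmp_path / "corpus")
    lexicons = default_lexicons(corpus_synonyms(pairs))
    report = evaluate_pair(documents, pairs[0], lexicons)
    assert not report.interaction_context_found
    assert report.proteins_co_mentioned  # excluded sentences still co-mention
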