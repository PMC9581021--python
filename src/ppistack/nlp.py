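"""Lightweight NLP primitives for the literature-evidence miner.

Self-contained sentence splitting, tokenization, stop-word removal, a
Porter stemmer, and a heuristic part-of-speech tagger (closed-class word
lists plus suffix rules). The tagger only needs to separate verbs and
nouns — the token classes the evidence rules consume — from everything
else; it is not a general-purpose tagger.
"""

from __future__ import annotations

import re
from typing import Iterable

_SENTENCE_END = re.compile(r"(?<=[.!?])\s+")
_TOKEN = re.compile(r"[A-Za-z][A-Za-z0-9\-]*")

STOP_WORDS = frozenset(
    """a about above after again all am an and any are as at be because been
    before being below between both but by could did do does doing down during
    each few for from further had has have having he her here hers him his how
    i if in into is it its itself just me more most my no nor not now of off
    on once only or other our ours out over own same she so some such than that
    the their theirs them then there these they this those through to too under
    until up very was we were what when where which while who whom why will
    with you your yours""".split()
)

# Closed-class and suffix cues for the heuristic tagger.
_MODALS = frozenset("can could may might must shall should will would".split())
_COMMON_VERBS = frozenset(
    """bind binds bound binding interact interacts interacted interacting
    recruit recruits recruited recruiting signal signals signaled signaling
    associate associates associated associating form forms formed forming
    phosphorylate phosphorylates phosphorylated regulate regulates regulated
    regulating activate activates activated activating inhibit inhibits
    inhibited inhibiting increase increases increased increasing decrease
    decreases decreased express expresses expressed expressing promote
    promotes promoted promoting induce induces induced show shows showed
    demonstrate demonstrates demonstrated observe observes observed suggest
    suggests suggested mediate mediates mediated co-immunoprecipitate
    co-immunoprecipitates co-immunoprecipitated colocalize colocalizes
    colocalized contain contains contained require requires required""".split()
)
_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ic", "ical")
_ADV_SUFFIX = "ly"
_VERB_SUFFIXES = ("ed", "ing", "izes", "ize", "ates", "ate", "ifies", "ify")


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation followed by whitespace."""
    return [s.strip() for s in _SENTENCE_END.split(text) if s.strip()]


def tokenize(sentence: str) -> list[str]:
    """Lowercased word tokens (letters, digits, internal hyphens)."""
    return [m.group(0).lower() for m in _TOKEN.finditer(sentence)]


def pos_tag(token: str) -> str:
    """Coarse tag: VERB, NOUN, ADJ, ADV or OTHER."""
    if token in _MODALS:
        return "OTHER"
    if token in _COMMON_VERBS:
        return "VERB"
    if token.endswith(_ADV_SUFFIX) and len(token) > 4:
        return "ADV"
    if token.endswith(_ADJ_SUFFIXES) and len(token) > 5:
        return "ADJ"
    if token.endswith(_VERB_SUFFIXES) and len(token) > 4:
        return "VERB"
    return "NOUN"


# ---------------------------------------------------------------------------
# Porter stemmer (classic 1980 algorithm, suffix-stripping in five steps).
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the stem (Porter's m)."""
    forms = "".join("c" if _is_consonant(stem, i) else "v" for i in range(len(stem)))
    return len(re.findall("vc", forms))


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, min_m: int) -> str | None:
    if word.endswith(suffix):
        stem = word[: len(word) - len(suffix)]
        if _measure(stem) > min_m:
            return stem + repl
        return word
    return None


def porter_stem(word: str) -> str:
    """Porter stem of a lowercase token; words of length <= 2 unchanged."""
    if len(word) <= 2:
        return word
    w = word

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_consonant(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif _measure(w) == 1 and _cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suffix, repl in (
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ):
        out = _replace(w, suffix, repl, 0)
        if out is not None:
            w = out
            break

    # step 3
    for suffix, repl in (
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ):
        out = _replace(w, suffix, repl, 0)
        if out is not None:
            w = out
            break

    # step 4
    for suffix in (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ):
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if _measure(stem) > 1:
                w = stem
            break
        if suffix == "ent" and w.endswith("ion"):
            pass
    if w.endswith("ion") and len(w) > 3 and w[-4] in "st" and _measure(w[:-3]) > 1:
        w = w[:-3]

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            w = stem
    # step 5b
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]

    return w


def stem_all(tokens: Iterable[str]) -> list[str]:
    return [porter_stem(t) for t in tokens]
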