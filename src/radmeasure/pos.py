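"""Whitespace/punctuation-aware tokenizer and a compact rule-based POS tagger.

The sequence labeler only needs coarse word-class evidence (noun vs adjective
vs number vs function word), so the tagger uses a closed-class lexicon, a few
domain words, and suffix heuristics over a small universal-style tagset:
NOUN, ADJ, VERB, ADV, NUM, DET, ADP, CONJ, PRON, PUNCT, X.
"""

from __future__ import annotations

import re
from .types import Token

_TOKEN_RE = re.compile(r"\d+(?:\.\d+)?|[A-Za-z]+(?:[-'][A-Za-z]+)*|\S")

_CLOSED_CLASS = {
    "the": "DET", "a": "DET", "an": "DET", "this": "DET", "that": "DET",
    "these": "DET", "those": "DET", "no": "DET",
    "of": "ADP", "in": "ADP", "on": "ADP", "at": "ADP", "by": "ADP",
    "to": "ADP", "from": "ADP", "with": "ADP", "within": "ADP",
    "for": "ADP", "near": "ADP", "along": "ADP", "without": "ADP",
    "and": "CONJ", "or": "CONJ", "but": "CONJ",
    "it": "PRON", "there": "PRON", "which": "PRON",
    "is": "VERB", "are": "VERB", "was": "VERB", "were": "VERB",
    "measures": "VERB", "measuring": "VERB", "measured": "VERB",
    "seen": "VERB", "noted": "VERB", "identified": "VERB", "demonstrates": "VERB",
    "now": "ADV", "previously": "ADV", "currently": "ADV", "today": "ADV",
    "again": "ADV", "not": "ADV", "example": "NOUN",
    "mm": "NOUN", "cm": "NOUN", "millimeter": "NOUN", "centimeter": "NOUN",
    "millimeters": "NOUN", "centimeters": "NOUN",
    "prior": "ADJ", "previous": "ADJ", "new": "ADJ", "stable": "ADJ",
    "x": "CONJ", "×": "CONJ",
}

_ADJ_SUFFIXES = ("ous", "ive", "ic", "al", "ar", "oid", "ated", "ing", "ed",
                 "dense", "intense", "echoic", "defined")


def pos_tag_word(word: str) -> str:
    low = word.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if re.fullmatch(r"\d+(?:\.\d+)?", word):
        return "NUM"
    if not any(c.isalnum() for c in word):
        return "PUNCT"
    if low.endswith("ly"):
        return "ADV"
    if low.endswith(_ADJ_SUFFIXES):
        return "ADJ"
    if word[0].isalpha():
        return "NOUN"
    return "X"


def tokenize(text: str) -> list[Token]:
    """Tokenize into numbers, hyphen-joined words, and single symbols."""
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def tokenize_and_pos(text: str) -> list[Token]:
    """Tokenize and attach POS tags; spans index the input text."""
    tokens = tokenize(text)
    for t in tokens:
        t.pos = pos_tag_word(t.surface)
    return tokens
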