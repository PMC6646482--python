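"""Corpus formats and training-sequence preparation.

Training data travels as JSON-lines standoff annotation: one object per
sentence, ``{"doc_id", "sent_id", "text", "entities": [{"start", "end",
"label"}]}`` with character spans into ``text``. A converter to/from
token-level BIO TSV (token TAB label, blank line between sentences) is
provided for interoperability with sequence-labeling tools.

``prepare_sequences`` replays the pipeline's own pre-processing on annotated
sentences — measurement/scan-reference tagging, sub-sentence division,
post-tagging normalization, tokenization — and projects the gold spans onto
tokens, so the CRF trains on exactly the representation it will see at
prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from . import measurements as meas
from .lexicons import Lexicons
from .ner import featurize, spans_to_bio
from .pos import tokenize_and_pos
from .preprocessing import map_span_to_normalized, normalize_after_tagging
from .types import Temporality, Token


@dataclass
class StandoffSentence:
    doc_id: str
    sent_id: int
    text: str
    entities: list[dict] = field(default_factory=list)  # {start, end, label}

    def to_json(self) -> str:
        return json.dumps(
            {"doc_id": self.doc_id, "sent_id": self.sent_id, "text": self.text,
             "entities": self.entities},
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, line: str) -> "StandoffSentence":
        d = json.loads(line)
        return cls(d["doc_id"], d.get("sent_id", 0), d["text"], d.get("entities", []))


def write_standoff(records: Iterable[StandoffSentence], path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_standoff(path: "str | Path") -> list[StandoffSentence]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(StandoffSentence.from_json(line))
    return out


def write_bio_tsv(sequences: Iterable[tuple[list[Token], list[str]]],
                  path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, labels in sequences:
            for tok, lab in zip(tokens, labels):
                fh.write(f"{tok.surface}\t{lab}\n")
            fh.write("\n")


def read_bio_tsv(path: "str | Path") -> list[tuple[list[str], list[str]]]:
    """Read BIO TSV back as (surfaces, labels) pairs (spans are not stored)."""
    sequences: list[tuple[list[str], list[str]]] = []
    words: list[str] = []
    labels: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                if words:
                    sequences.append((words, labels))
                    words, labels = [], []
                continue
            surface, _, lab = line.partition("\t")
            words.append(surface)
            labels.append(lab)
    if words:
        sequences.append((words, labels))
    return sequences


@dataclass
class PreparedSequence:
    doc_id: str
    sent_id: int
    norm_text: str
    tokens: list[Token]
    features: list[dict]
    labels: list[str]  # gold BIO; empty when the record has no gold entities


def _iter_subsentences(text: str):
    """Yield (sub_start, sub_end, protected spans, rule spans) for a sentence.

    Protected spans are measurement mentions and scan references; rule spans
    additionally carry the rule-assigned type (for transition analysis) plus
    the temporality cue spans.
    """
    mentions = meas.tag_measurements(text)
    refs = meas.tag_scan_references(text)
    ref_spans = {(r.start, r.end) for r in refs}
    mention_spans = {(m.start, m.end) for m in mentions}
    # discard refs nested inside a measurement (cannot happen by grammar, but be safe)
    meas.tag_temporality(text, mentions)
    if mentions:
        subs = [(s.start, s.end) for s in meas.divide_subsentences(text, mentions)]
    else:
        subs = [(0, len(text))]
    rule_spans: list[tuple[int, int, str]] = []
    for m in mentions:
        rule_spans.append((m.start, m.end, "MEASUREMENT"))
        if m.cue_span is not None:
            rule_spans.append((m.cue_span[0], m.cue_span[1], "TEMPORALITY"))
    for r in refs:
        rule_spans.append((r.start, r.end, r.kind.value))
    protected = sorted(mention_spans | ref_spans)
    for a, b in subs:
        local_protected = [
            (max(s, a) - a, min(e, b) - a) for s, e in protected if s < b and e > a
        ]
        local_rules = [
            (max(s, a) - a, min(e, b) - a, t) for s, e, t in rule_spans if s < b and e > a
        ]
        yield a, b, local_protected, local_rules


def prepare_sequences(
    records: Iterable[StandoffSentence],
    lexicons: Lexicons,
    include_rule_labels: bool = False,
    require_measurement: bool = True,
) -> list[PreparedSequence]:
    """Turn standoff sentences into aligned (features, BIO labels) sequences.

    Sentences without a tagged measurement are skipped by default, matching
    the pipeline's restriction to measurement-bearing sentences. Each
    sub-sentence becomes one sequence. With ``include_rule_labels`` the
    rule-tagged measurement/image/series/segment/temporality spans join the
    label set (used for transition-score analysis).
    """
    out: list[PreparedSequence] = []
    for rec in records:
        text = rec.text
        had_measurement = bool(meas.MEASUREMENT_RE.search(text))
        if require_measurement and not had_measurement:
            continue
        for a, b, protected, rules in _iter_subsentences(text):
            sub_text = text[a:b]
            norm, omap = normalize_after_tagging(sub_text, protected)
            tokens = tokenize_and_pos(norm)
            if not tokens:
                continue
            spans: list[tuple[int, int, str]] = []
            for ent in rec.entities:
                s, e = ent["start"] - a, ent["end"] - a
                if e <= 0 or s >= len(sub_text):
                    continue
                mapped = map_span_to_normalized((max(s, 0), min(e, len(sub_text))), omap)
                if mapped:
                    spans.append((mapped[0], mapped[1], ent["label"]))
            if include_rule_labels:
                for s, e, t in rules:
                    mapped = map_span_to_normalized((s, e), omap)
                    if mapped:
                        spans.append((mapped[0], mapped[1], t))
            labels = spans_to_bio(tokens, spans)
            out.append(
                PreparedSequence(
                    doc_id=rec.doc_id, sent_id=rec.sent_id, norm_text=norm,
                    tokens=tokens, features=featurize(tokens, lexicons), labels=labels,
                )
            )
    return out
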