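"""Report pre-processing: section segmentation, sentence splitting, normalization.

Narrative radiology reports are organized under conventional headers
(Comparison, Technique, Clinical History, Findings, Conclusions/Impression).
Lesion measurements live in the Findings section, so the pipeline segments the
report by header, selects Findings, and splits it into sentences with stable
character offsets back into the raw text. Lowercasing and punctuation removal
happen only *after* measurement tagging, so that size expressions like
"1.2 x 3.4 cm" and references like "(image 127)" survive intact.
"""

from __future__ import annotations

import re
import string
from typing import Iterable, Sequence

from .types import Report, Section, SectionName, Sentence

# Header dialects, matched case-insensitively at line starts or after sentence
# breaks, with an optional trailing colon. Order within a tuple is irrelevant.
DEFAULT_HEADER_PATTERNS: dict[str, list[str]] = {
    SectionName.COMPARISON.value: [r"comparison"],
    SectionName.TECHNIQUE.value: [r"technique", r"procedure"],
    SectionName.CLINICAL_HISTORY.value: [r"clinical\s+history", r"history", r"indication"],
    SectionName.FINDINGS.value: [r"findings?"],
    SectionName.CONCLUSIONS.value: [r"conclusions?", r"impression"],
}

_PUNCT = set(string.punctuation)


def _compile_header_regex(patterns: dict[str, list[str]]) -> re.Pattern:
    alts = []
    for name, pats in patterns.items():
        alts.append("(?P<%s>%s)" % (name, "|".join(pats)))
    # Header must start a line (possibly after whitespace) or follow a sentence
    # boundary, and ends with a colon or an end of line.
    body = "|".join(alts)
    return re.compile(
        r"(?:(?<=^)|(?<=[\n\r])|(?<=[.!?]\s))\s*(?:%s)\s*(?::|(?=\s*$))" % body,
        re.IGNORECASE | re.MULTILINE,
    )


def segment_sections(
    raw_text: str, header_patterns: dict[str, list[str]] | None = None
) -> list[Section]:
    """Split a report into sections by recognized headers.

    Text before the first recognized header becomes an OTHER section; each
    section's body runs from the end of its header to the start of the next
    header (or the end of text). Empty input yields an empty list.
    """
    if not raw_text:
        return []
    rx = _compile_header_regex(header_patterns or DEFAULT_HEADER_PATTERNS)
    matches = list(rx.finditer(raw_text))
    sections: list[Section] = []
    if not matches:
        return [Section(SectionName.OTHER, 0, len(raw_text))]
    if matches[0].start() > 0 and raw_text[: matches[0].start()].strip():
        sections.append(Section(SectionName.OTHER, 0, matches[0].start()))
    for i, m in enumerate(matches):
        name = SectionName.OTHER
        for candidate in SectionName:
            if candidate is SectionName.OTHER:
                continue
            if m.group(candidate.value) is not None:
                name = candidate
                break
        end = matches[i + 1].start() if i + 1 < len(matches) else len(raw_text)
        sections.append(Section(name, m.end(), end, header_span=(m.start(), m.end())))
    return sections


def make_report(doc_id: str, raw_text: str,
                header_patterns: dict[str, list[str]] | None = None) -> Report:
    return Report(doc_id=doc_id, raw_text=raw_text,
                  sections=segment_sections(raw_text, header_patterns))


def select_findings(report: Report) -> list[Section]:
    """Return the FINDINGS sections, or the OTHER fallback when none exist.

    Mammography-style reports often carry no CT-style headers; falling back to
    the whole body lets their measurements be processed anyway.
    """
    found = [s for s in report.sections if s.name is SectionName.FINDINGS]
    if found:
        return found
    return [s for s in report.sections if s.name is SectionName.OTHER]


# Sentence splitting ---------------------------------------------------------

_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "vs", "e.g", "i.e", "cf", "approx", "no",
    "fig", "figs", "st", "ref", "seq", "max", "min",
}

_SENT_BOUNDARY = re.compile(r"[.!?]+")


def split_sentences(text: str, base_offset: int = 0) -> list[Sentence]:
    """Split section text into sentences with offsets into the raw report text.

    The splitter never breaks inside parentheses, after a decimal point, after
    a single-letter or known abbreviation, or when the terminator is not
    followed by whitespace + an uppercase/digit start. This keeps long Findings
    sentences with internal parentheticals and semicolons in one piece.
    """
    sentences: list[Sentence] = []
    if not text.strip():
        return sentences
    starts: list[int] = []
    n = len(text)
    depth = 0
    boundaries: list[int] = []
    for m in _SENT_BOUNDARY.finditer(text):
        i, j = m.start(), m.end()
        # track parenthesis depth up to this point lazily
        depth = text.count("(", 0, i) - text.count(")", 0, i)
        if depth > 0:
            continue
        if text[i] == ".":
            # decimal number: digit on both sides
            if i > 0 and text[i - 1].isdigit() and j < n and text[j:j + 1].isdigit():
                continue
            word = re.search(r"([A-Za-z][A-Za-z.]*)$", text[:i])
            if word:
                w = word.group(1).lower().rstrip(".")
                if len(w) == 1 or w in _ABBREVIATIONS:
                    continue
        tail = text[j:]
        if tail and not re.match(r"\s", tail):
            continue
        boundaries.append(j)
    boundaries.append(n)
    prev = 0
    sent_id = 0
    for b in boundaries:
        chunk = text[prev:b]
        stripped = chunk.strip()
        if stripped:
            s = prev + (len(chunk) - len(chunk.lstrip()))
            e = s + len(stripped)
            sentences.append(Sentence(sent_id, base_offset + s, base_offset + e, stripped))
            sent_id += 1
        prev = b
    return sentences


def split_section_sentences(report: Report, section: Section) -> list[Sentence]:
    return split_sentences(report.raw_text[section.start:section.end], section.start)


# Post-tagging normalization -------------------------------------------------

def normalize_after_tagging(
    sentence_text: str, protected_spans: Sequence[tuple[int, int]]
) -> tuple[str, list[int]]:
    """Lowercase and strip punctuation outside protected spans.

    Returns the normalized string and an offset map: ``offset_map[i]`` is the
    index in ``sentence_text`` of the character that produced normalized
    character ``i``. Whitespace runs collapse to a single space; protected
    spans (already-tagged measurements and image/series/segment references)
    are copied verbatim. Overlapping protected spans signal an inconsistent
    tagger and raise ``ValueError``.
    """
    spans = sorted(protected_spans)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if b1 > a2:
            raise ValueError(f"overlapping protected spans {(a1, b1)} and {(a2, b2)}")
    for a, b in spans:
        if a < 0 or b > len(sentence_text) or a > b:
            raise ValueError(f"protected span {(a, b)} outside sentence")

    protected = [False] * len(sentence_text)
    for a, b in spans:
        for i in range(a, b):
            protected[i] = True

    out: list[str] = []
    offset_map: list[int] = []
    pending_space: int | None = None  # original index of a pending collapsed space
    for i, ch in enumerate(sentence_text):
        if protected[i]:
            if pending_space is not None and out:
                out.append(" ")
                offset_map.append(pending_space)
            pending_space = None
            out.append(ch)
            offset_map.append(i)
            continue
        if ch.isspace():
            if pending_space is None:
                pending_space = i
            continue
        if ch in _PUNCT:
            continue
        if pending_space is not None and out:
            out.append(" ")
            offset_map.append(pending_space)
        pending_space = None
        out.append(ch.lower())
        offset_map.append(i)
    return "".join(out), offset_map


def map_span_to_original(span: tuple[int, int], offset_map: list[int]) -> tuple[int, int]:
    """Map a span in normalized coordinates back to the original sentence."""
    s, e = span
    if s >= e:
        return (offset_map[s] if s < len(offset_map) else len(offset_map),) * 2
    return (offset_map[s], offset_map[e - 1] + 1)


def map_span_to_normalized(span: tuple[int, int], offset_map: list[int]) -> tuple[int, int] | None:
    """Map an original-coordinate span into normalized coordinates.

    Returns None when every character of the span was removed.
    """
    s, e = span
    idxs = [i for i, o in enumerate(offset_map) if s <= o < e]
    if not idxs:
        return None
    return (idxs[0], idxs[-1] + 1)
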