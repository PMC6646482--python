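"""Measurement, temporality and scan-reference tagging; sub-sentence division.

A measurement mention is a maximal textual size expression of one to three
dimensions ("4 mm", "4-5 mm", "1.2 x 3.4 x 2.0 cm", "4 mm x 5 mm"). Its
temporality says whether it describes the current scan (CURRENT) or quotes an
earlier study (PRIOR, e.g. "previously 7 mm"). Sentences reporting several
measurements are divided into sub-sentences — one measurement each — which
become the scope for descriptor linking downstream.

All spans returned here index the sentence text handed in.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .types import (
    Dimension,
    MeasurementMention,
    ScanRefKind,
    ScanReference,
    Sentence,
    SubSentence,
    Temporality,
)

_NUM = r"\d+(?:\.\d+)?"
_RANGE = rf"{_NUM}(?:\s*-\s*{_NUM})?"
# Long unit forms first so "mm" cannot truncate "millimeter".
_UNIT = r"(?:millimeters?|centimeters?|mm|cm)"
_DIM_OPT_UNIT = rf"{_RANGE}(?:\s*{_UNIT}(?![A-Za-z]))?"

# Up to three joined dimensions; the final one must carry a unit so bare
# number pairs ("4 x 5") never trigger.
MEASUREMENT_RE = re.compile(
    rf"(?<![\w.])(?:{_DIM_OPT_UNIT}\s*[x×]\s*){{0,2}}{_RANGE}\s*{_UNIT}(?![A-Za-z])",
    re.IGNORECASE,
)

_DIM_RE = re.compile(
    rf"(?P<a>{_NUM})(?:\s*-\s*(?P<b>{_NUM}))?(?:\s*(?P<unit>{_UNIT})(?![A-Za-z]))?",
    re.IGNORECASE,
)


def _normalize_unit(unit: str) -> str:
    unit = unit.lower()
    if unit.startswith("milli") or unit == "mm":
        return "mm"
    return "cm"


def _text_of(sentence) -> str:
    return sentence.text if isinstance(sentence, Sentence) else sentence


def tag_measurements(sentence: "Sentence | str") -> list[MeasurementMention]:
    """Tag every maximal size expression in a raw (pre-normalization) sentence.

    Multi-dimension forms collapse into a single mention; ranges ("4-5 mm")
    become one mention valued at the larger endpoint. Matches never overlap
    and are returned in reading order with temporality unset.
    """
    text = _text_of(sentence)
    mentions: list[MeasurementMention] = []
    for m in MEASUREMENT_RE.finditer(text):
        dims: list[Dimension] = []
        shared_unit: Optional[str] = None
        raw_dims = []
        for dm in _DIM_RE.finditer(m.group(0)):
            raw_dims.append(dm)
            if dm.group("unit"):
                shared_unit = _normalize_unit(dm.group("unit"))
        for dm in raw_dims:
            unit = _normalize_unit(dm.group("unit")) if dm.group("unit") else shared_unit
            values = [float(dm.group("a"))]
            if dm.group("b"):
                values.append(float(dm.group("b")))
            dims.append(
                Dimension(
                    value=max(values),
                    unit=unit or "mm",
                    start=m.start() + dm.start(),
                    end=m.start() + dm.end(),
                )
            )
        mentions.append(
            MeasurementMention(
                mention_id=len(mentions),
                dimensions=dims,
                start=m.start(),
                end=m.end(),
                surface=m.group(0),
            )
        )
    return mentions


# Temporality ----------------------------------------------------------------

_DATE_LIKE = r"(?:\d{1,2}/\d{1,2}/\d{2,4}|(?:jan|feb|mar|apr|may|jun|jul|aug|sep|oct|nov|dec)[a-z]*\.?\s+\d{1,4})"

DEFAULT_PRIOR_CUES = [
    r"previously",
    r"previous",
    r"prior",
    r"was",
    r"compared\s+(?:to|with)",
    rf"from\s+{_DATE_LIKE}",
]
DEFAULT_CURRENT_CUES = [r"now", r"currently", r"today"]


def _cue_regex(cues: Sequence[str]) -> re.Pattern:
    return re.compile(r"\b(?:%s)\b" % "|".join(cues), re.IGNORECASE)


def _closing_paren(text: str, pos: int) -> Optional[int]:
    """Index just past the ')' closing the innermost '(' open at ``pos``."""
    depth = 0
    opens: list[int] = []
    for i, ch in enumerate(text[:pos]):
        if ch == "(":
            opens.append(i)
        elif ch == ")" and opens:
            opens.pop()
    if not opens:
        return None
    depth = 1
    for i in range(pos, len(text)):
        if text[i] == "(":
            depth += 1
        elif text[i] == ")":
            depth -= 1
            if depth == 0:
                return i + 1
    return None


def _prior_scope_end(text: str, cue_start: int, next_cue_start: Optional[int]) -> int:
    end = len(text)
    close = _closing_paren(text, cue_start)
    if close is not None:
        end = min(end, close)
    if next_cue_start is not None:
        end = min(end, next_cue_start)
    return end


def tag_temporality(
    sentence: "Sentence | str",
    mentions: list[MeasurementMention],
    prior_cues: Sequence[str] | None = None,
    current_cues: Sequence[str] | None = None,
) -> list[MeasurementMention]:
    """Label each mention CURRENT or PRIOR from lexical cues.

    A mention is PRIOR iff the last cue preceding it is a prior cue whose
    scope still covers it. A prior cue's scope runs to the next cue of either
    polarity, to the parenthesis that closes around it, or to sentence end;
    mentions with no governing cue default to CURRENT.
    """
    text = _text_of(sentence)
    prior_rx = _cue_regex(prior_cues or DEFAULT_PRIOR_CUES)
    current_rx = _cue_regex(current_cues or DEFAULT_CURRENT_CUES)
    cues = [(m.start(), m.end(), Temporality.PRIOR) for m in prior_rx.finditer(text)]
    cues += [(m.start(), m.end(), Temporality.CURRENT) for m in current_rx.finditer(text)]
    cues.sort()
    for mention in mentions:
        mention.temporality = Temporality.CURRENT
        mention.cue_span = None
        governing = None
        nxt = None
        for i, cue in enumerate(cues):
            if cue[0] < mention.start:
                governing = cue
                nxt = cues[i + 1][0] if i + 1 < len(cues) else None
            else:
                break
        if governing and governing[2] is Temporality.PRIOR:
            scope_end = _prior_scope_end(text, governing[0], nxt)
            if mention.start < scope_end:
                mention.temporality = Temporality.PRIOR
                mention.cue_span = (governing[0], governing[1])
    return mentions


# Sub-sentence division ------------------------------------------------------

def _delimiter_candidates(text: str, lo: int, hi: int) -> list[tuple[int, str]]:
    """Boundary candidates in the gap [lo, hi): after ')', ',' and ';'; before '('."""
    out = []
    for i in range(lo, hi):
        ch = text[i]
        if ch == ")":
            out.append((i + 1, "paren"))
        elif ch == "(":
            out.append((i, "paren"))
        elif ch in ",;":
            out.append((i + 1, "comma"))
    return [(p, k) for p, k in out if lo <= p <= hi]


def _midpoint(text: str, lo: int, hi: int) -> int:
    mid = (lo + hi) // 2
    best, dist = mid, None
    for i in range(lo, hi):
        if text[i].isspace():
            d = abs(i - mid)
            if dist is None or d < dist:
                best, dist = i, d
    return best


def divide_subsentences(
    sentence: "Sentence | str", mentions: list[MeasurementMention], sent_id: int = 0
) -> list[SubSentence]:
    """Divide a sentence into one sub-sentence per measurement.

    Boundaries fall in the gap between consecutive mentions. A boundary keeps
    a prior cue with its prior mention: when the following mention is PRIOR
    with its cue in the gap, the latest delimiter before the cue is used; when
    the preceding mention's prior scope closes inside the gap, the earliest
    delimiter after the scope end is used. Otherwise parenthesis delimiters
    are preferred, then commas/semicolons, then the whitespace nearest the
    midpoint. Sub-sentence spans partition the whole sentence.
    """
    text = _text_of(sentence)
    if isinstance(sentence, Sentence):
        sent_id = sentence.sent_id
    if not mentions:
        return []
    mentions = sorted(mentions, key=lambda m: m.start)
    boundaries: list[int] = []
    for m1, m2 in zip(mentions, mentions[1:]):
        lo, hi = m1.end, m2.start
        cands = _delimiter_candidates(text, lo, hi)
        boundary: Optional[int] = None
        cue_in_gap = (
            m2.temporality is Temporality.PRIOR
            and m2.cue_span is not None
            and lo <= m2.cue_span[0] < hi
        )
        scope_end = None
        if m1.temporality is Temporality.PRIOR and m1.cue_span is not None:
            se = _prior_scope_end(text, m1.cue_span[0], None)
            if lo <= se <= hi:
                scope_end = se
        if cue_in_gap:
            cue_start = m2.cue_span[0]
            valid = [p for p, _ in cands if p <= cue_start]
            if scope_end is not None:
                after = [p for p in valid if p >= scope_end]
                valid = after or valid
            boundary = max(valid) if valid else cue_start
        elif scope_end is not None:
            valid = [p for p, _ in cands if p >= scope_end]
            boundary = min(valid) if valid else scope_end
        elif cands:
            parens = [p for p, k in cands if k == "paren"]
            commas = [p for p, k in cands if k == "comma"]
            boundary = parens[0] if parens else commas[0]
        else:
            boundary = _midpoint(text, lo, hi)
        boundaries.append(min(max(boundary, lo), hi))
    starts = [0] + boundaries
    ends = boundaries + [len(text)]
    subs = []
    for m, s, e in zip(mentions, starts, ends):
        if not (s <= m.start and m.end <= e):
            raise AssertionError("sub-sentence boundary cut through a measurement")
        subs.append(SubSentence(sent_id=sent_id, start=s, end=e, measurement=m))
    return subs


# Image / series / segment references ---------------------------------------

SCAN_REF_RE = re.compile(
    r"\b(?:(?P<image>images?|img|im)|(?P<series>series|ser|se)|(?P<segment>segments?|seg))\b"
    r"\s*[#:]?\s*(?P<num>\d+)(?:\s*-\s*(?P<num2>\d+))?"
    r"(?!\s*(?:millimeter|centimeter|mm|cm))",
    re.IGNORECASE,
)


def tag_scan_references(sentence: "Sentence | str") -> list[ScanReference]:
    """Tag image/series/segment references ("image 127", "series 11", "seg 5").

    A numeric tail is required, so prose like "imaging was performed" never
    triggers. Ranges keep the first number and the full surface.
    """
    text = _text_of(sentence)
    refs: list[ScanReference] = []
    for m in SCAN_REF_RE.finditer(text):
        if m.group("image"):
            kind = ScanRefKind.IMAGE
        elif m.group("series"):
            kind = ScanRefKind.SERIES
        else:
            kind = ScanRefKind.SEGMENT
        refs.append(
            ScanReference(
                kind=kind,
                number=int(m.group("num")),
                start=m.start(),
                end=m.end(),
                surface=m.group(0),
            )
        )
    return refs
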