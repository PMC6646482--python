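"""Frame assembly: link each measurement to its seven descriptors.

Every measurement becomes one frame holding the numeric size plus seven
descriptor slots: temporality, anatomical entity, imaging observation,
RadLex descriptor, image number, series number, organ segment. Linking is
rule-based and scoped to the measurement's sub-sentence — the sentence
division step exists precisely to bound this scope — with two exceptions:

* image/series/segment slots fall back to sentence-level references (a
  leading "series 11" is shared by every measurement in the sentence), and
* a PRIOR frame whose own sub-sentence names no entities inherits the
  anatomical entity / imaging observation of the nearest preceding CURRENT
  frame, since a quoted prior size ("previously 7 mm") describes the same
  finding.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import IO, Iterable, Optional

from . import measurements as meas
from .crf import LinearChainCRF
from .lexicons import Lexicons
from .ner import dictionary_tag, featurize, labels_to_entities, predict_labels
from .pos import tokenize_and_pos
from .preprocessing import (
    make_report,
    map_span_to_original,
    normalize_after_tagging,
    select_findings,
    split_section_sentences,
)
from .types import (
    EntityMention,
    EntityType,
    MeasurementFrame,
    Report,
    ScanRefKind,
    ScanReference,
    SubSentence,
    Temporality,
)

FRAME_SCHEMA = "radmeasure-frame-1"

_SLOT_BY_TYPE = {
    EntityType.ANATOMICAL_ENTITY: "anatomical_entity",
    EntityType.IMAGING_OBSERVATION: "imaging_observation",
    EntityType.RADLEX_DESCRIPTOR: "radlex_descriptor",
}
_SLOT_BY_KIND = {
    ScanRefKind.IMAGE: "image_number",
    ScanRefKind.SERIES: "series_number",
    ScanRefKind.SEGMENT: "segment",
}


def _gap(span_a: tuple[int, int], span_b: tuple[int, int]) -> int:
    if span_a[1] <= span_b[0]:
        return span_b[0] - span_a[1]
    if span_b[1] <= span_a[0]:
        return span_a[0] - span_b[1]
    return 0


def _nearest(refs: list[ScanReference], kind: ScanRefKind,
             anchor: tuple[int, int]) -> Optional[int]:
    best = None
    best_d = None
    for r in refs:
        if r.kind is not kind:
            continue
        d = _gap(r.span, anchor)
        if best_d is None or d < best_d:
            best, best_d = r.number, d
    return best


def link_descriptors(
    subsentence: SubSentence,
    entities: list[EntityMention],
    scan_refs: list[ScanReference],
    sentence_scope_refs: list[ScanReference],
    doc_id: str = "",
    frame_id: str = "",
) -> MeasurementFrame:
    """Populate one frame from its sub-sentence.

    ``entities`` and ``scan_refs`` must already be restricted to spans
    overlapping the sub-sentence; ``sentence_scope_refs`` are sentence-level
    image/series/segment references shared by all sub-sentences. Numeric
    slots take the nearest in-sub-sentence reference, else the nearest
    sentence-scope one.
    """
    m = subsentence.measurement
    if not (subsentence.start <= m.start and m.end <= subsentence.end):
        raise ValueError("sub-sentence does not own its measurement")
    frame = MeasurementFrame(
        frame_id=frame_id or f"{doc_id}:{subsentence.sent_id}:{m.mention_id}",
        doc_id=doc_id,
        sentence_id=subsentence.sent_id,
        value=m.value,
        unit=m.unit,
        dimensions=[d.value for d in m.dimensions],
        measurement_span=m.span,
        surface=m.surface,
        temporality=(m.temporality or Temporality.CURRENT).value,
    )
    for ent in sorted(entities, key=lambda e: e.start):
        if ent.end > m.start and ent.start < m.end:
            continue  # the measurement itself is never its own descriptor
        slot = getattr(frame, _SLOT_BY_TYPE[ent.type])
        if ent.surface not in slot:
            slot.append(ent.surface)
    for kind, slot in _SLOT_BY_KIND.items():
        number = _nearest(scan_refs, kind, m.span)
        if number is None:
            number = _nearest(sentence_scope_refs, kind, m.span)
        setattr(frame, slot, number)
    return frame


def _sentence_frames(
    doc_id: str,
    sent_id: int,
    text: str,
    lexicons: Lexicons,
    model: Optional[LinearChainCRF],
    prior_cues=None,
    current_cues=None,
) -> list[MeasurementFrame]:
    mentions = meas.tag_measurements(text)
    if not mentions:
        return []
    meas.tag_temporality(text, mentions, prior_cues, current_cues)
    refs = meas.tag_scan_references(text)
    subs = meas.divide_subsentences(text, mentions, sent_id=sent_id)
    scope_refs = [r for r in refs if r.start < mentions[0].start]
    frames: list[MeasurementFrame] = []
    for sub in subs:
        local_refs = [r for r in refs if r.start < sub.end and r.end > sub.start]
        protected = sorted(
            {(sub.measurement.start - sub.start, sub.measurement.end - sub.start)}
            | {(max(r.start, sub.start) - sub.start, min(r.end, sub.end) - sub.start)
               for r in local_refs}
        )
        sub_text = text[sub.start:sub.end]
        norm, omap = normalize_after_tagging(sub_text, protected)
        tokens = tokenize_and_pos(norm)
        if model is None:
            ents_norm = dictionary_tag(tokens, lexicons, norm)
        else:
            labels = predict_labels(model, featurize(tokens, lexicons))
            ents_norm = labels_to_entities(tokens, labels, norm)
        entities = []
        for e in ents_norm:
            s, t = map_span_to_original((e.start, e.end), omap)
            entities.append(
                EntityMention(e.type, sub.start + s, sub.start + t, sub_text[s:t])
            )
        frames.append(
            link_descriptors(sub, entities, local_refs, scope_refs, doc_id=doc_id)
        )
    # PRIOR frames with empty entity slots inherit from the nearest preceding
    # CURRENT frame of the same sentence.
    for i, frame in enumerate(frames):
        if frame.temporality != Temporality.PRIOR.value:
            continue
        donor = None
        for j in range(i - 1, -1, -1):
            if frames[j].temporality == Temporality.CURRENT.value:
                donor = frames[j]
                break
        if donor is None:
            continue
        if not frame.anatomical_entity:
            frame.anatomical_entity = list(donor.anatomical_entity)
        if not frame.imaging_observation:
            frame.imaging_observation = list(donor.imaging_observation)
    return frames


def build_frames(
    report: "Report | str",
    lexicons: Lexicons,
    model: Optional[LinearChainCRF] = None,
    doc_id: str = "report",
    prior_cues=None,
    current_cues=None,
) -> list[MeasurementFrame]:
    """Run the full pipeline on one report and return frames in reading order.

    With ``model=None`` the dictionary baseline tags entities; otherwise the
    trained CRF does. Accepts a ready ``Report`` or raw text.
    """
    if isinstance(report, str):
        report = make_report(doc_id, report)
    frames: list[MeasurementFrame] = []
    for section in select_findings(report):
        for sentence in split_section_sentences(report, section):
            frames.extend(
                _sentence_frames(
                    report.doc_id, sentence.sent_id, sentence.text, lexicons,
                    model, prior_cues, current_cues,
                )
            )
    return frames


# -- serialization -----------------------------------------------------------

def serialize_frames(frames: Iterable[MeasurementFrame], stream: IO[str]) -> None:
    """Write frames as schema-versioned JSON lines (lossless round trip)."""
    for frame in frames:
        record = {"schema": FRAME_SCHEMA, **frame.to_dict()}
        stream.write(json.dumps(record, ensure_ascii=False) + "\n")


def write_frames(frames: Iterable[MeasurementFrame], path: "str | Path") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        serialize_frames(frames, fh)


def parse_frames(stream: IO[str]) -> list[MeasurementFrame]:
    return [MeasurementFrame.from_dict(json.loads(line))
            for line in stream if line.strip()]


def read_frames(path: "str | Path") -> list[MeasurementFrame]:
    with open(path, encoding="utf-8") as fh:
        return parse_frames(fh)


def frames_to_table(frames: list[MeasurementFrame]):
    """Flat CSV-ready view: one row per frame, list slots joined with '|'."""
    import pandas as pd

    rows = []
    for f in frames:
        d = f.to_dict()
        for slot in ("anatomical_entity", "imaging_observation", "radlex_descriptor"):
            d[slot] = "|".join(d[slot])
        d["dimensions"] = "x".join(str(v) for v in d["dimensions"])
        d["measurement_span"] = f"{f.measurement_span[0]}:{f.measurement_span[1]}"
        rows.append(d)
    return pd.DataFrame(rows)
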