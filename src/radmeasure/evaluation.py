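"""Scoring of system frames against gold annotations.

Two granularities, mirroring how such pipelines are reported:

* sentence-level precision/recall/F per information type (the measurement
  itself and each of the seven descriptors), from TP/FP/FN counts; and
* report-level full / partial / no match per measurement: FULL when every
  gold descriptor is matched, PARTIAL when at least one is matched and at
  least one missed, NO_MATCH when none is.

System and gold frames align when their measurement spans overlap and their
value+unit agree. Text slots compare exactly after lowercasing and
whitespace collapse; numeric slots by equality; temporality by label.
Descriptors absent from both sides are vacuously satisfied.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import (
    DESCRIPTOR_NAMES,
    ConfusionCounts,
    MatchCategory,
    MatchResult,
    MeasurementFrame,
    MetricsRow,
)

_LIST_SLOTS = ("anatomical_entity", "imaging_observation", "radlex_descriptor")
_NUMERIC_SLOTS = ("image_number", "series_number", "segment")


def _norm(s: str) -> str:
    return " ".join(s.lower().split())


def metrics_from_counts(c: ConfusionCounts,
                        information_type: str = "") -> MetricsRow:
    """Precision/recall/F as percentages; undefined denominators yield None."""
    precision = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f = None if (precision is None or recall is None) else 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return MetricsRow(information_type, precision, recall, f)


# -- frame alignment ---------------------------------------------------------

def _spans_overlap(a: tuple, b: tuple) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _alignable(s: MeasurementFrame, g: MeasurementFrame) -> bool:
    return (
        s.doc_id == g.doc_id
        and s.sentence_id == g.sentence_id
        and _spans_overlap(tuple(s.measurement_span), tuple(g.measurement_span))
        and s.value == g.value
        and s.unit == g.unit
    )


def _descriptor_state(s: MeasurementFrame, g: MeasurementFrame,
                      name: str) -> Optional[bool]:
    """True=matched, False=missed, None=absent from gold (vacuous)."""
    if name == "temporality":
        return s.temporality == g.temporality
    if name in _LIST_SLOTS:
        gold = [_norm(v) for v in g.descriptor(name)]
        if not gold:
            return None
        have = {_norm(v) for v in s.descriptor(name)}
        return all(v in have for v in gold)
    gold = g.descriptor(name)
    if gold is None:
        return None
    return s.descriptor(name) == gold


def _match_count(s: MeasurementFrame, g: MeasurementFrame) -> int:
    return sum(1 for n in DESCRIPTOR_NAMES if _descriptor_state(s, g, n) is True)


def align_frames(
    system: Sequence[MeasurementFrame], gold: Sequence[MeasurementFrame]
) -> tuple[list[tuple[MeasurementFrame, MeasurementFrame]],
           list[MeasurementFrame], list[MeasurementFrame]]:
    """Greedy best-scoring one-to-one pairing of system and gold frames.

    Candidate pairs need overlapping measurement spans and equal value+unit;
    among candidates the pairing with the most matched descriptors wins,
    leftmost (document-order) on ties. Returns (pairs, unmatched system,
    unmatched gold).
    """
    candidates = []
    for si, s in enumerate(system):
        for gi, g in enumerate(gold):
            if _alignable(s, g):
                candidates.append((-_match_count(s, g), si, gi))
    candidates.sort()
    used_s: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for _, si, gi in candidates:
        if si in used_s or gi in used_g:
            continue
        used_s.add(si)
        used_g.add(gi)
        pairs.append((system[si], gold[gi]))
    unmatched_s = [s for i, s in enumerate(system) if i not in used_s]
    unmatched_g = [g for i, g in enumerate(gold) if i not in used_g]
    return pairs, unmatched_s, unmatched_g


# -- descriptor-level counts -------------------------------------------------

def score_descriptor(
    system: Sequence[MeasurementFrame],
    gold: Sequence[MeasurementFrame],
    descriptor: str,
) -> ConfusionCounts:
    """TP/FP/FN for one information type over aligned frames.

    ``descriptor`` may be "measurement" (alignment itself) or any of the
    seven descriptor slots. Values on unaligned system frames count as FP;
    values on unaligned gold frames as FN.
    """
    pairs, un_s, un_g = align_frames(system, gold)
    c = ConfusionCounts()
    if descriptor == "measurement":
        return ConfusionCounts(tp=len(pairs), fp=len(un_s), fn=len(un_g))
    if descriptor not in DESCRIPTOR_NAMES:
        raise ValueError(f"unknown descriptor {descriptor!r}")

    def values(frame):
        if descriptor == "temporality":
            return [frame.temporality]
        if descriptor in _LIST_SLOTS:
            return [_norm(v) for v in frame.descriptor(descriptor)]
        v = frame.descriptor(descriptor)
        return [] if v is None else [v]

    for s, g in pairs:
        sv, gv = list(values(s)), list(values(g))
        for v in gv:
            if v in sv:
                sv.remove(v)
                c.tp += 1
            else:
                c.fn += 1
        c.fp += len(sv)
    for s in un_s:
        c.fp += len(values(s))
    for g in un_g:
        c.fn += len(values(g))
    return c


INFORMATION_TYPES = ("measurement",) + DESCRIPTOR_NAMES


def metrics_table(system: Sequence[MeasurementFrame],
                  gold: Sequence[MeasurementFrame]) -> pd.DataFrame:
    rows = []
    for info in INFORMATION_TYPES:
        row = metrics_from_counts(score_descriptor(system, gold, info), info).rounded()
        rows.append({"information_type": info, "precision": row.precision,
                     "recall": row.recall, "f_score": row.f_score})
    return pd.DataFrame(rows)


# -- full / partial / no match ----------------------------------------------

def classify_match(system: Optional[MeasurementFrame],
                   gold: MeasurementFrame) -> MatchResult:
    """Classify one gold measurement given its aligned system frame (or None).

    FULL: measurement matched and no gold descriptor missed. NO_MATCH: the
    system matched neither the measurement's descriptors nor anything else
    (or produced no frame at all). PARTIAL: anything in between. Descriptors
    absent from both sides count toward FULL.
    """
    if system is None:
        return MatchResult(gold.frame_id, MatchCategory.NO_MATCH,
                           frozenset(), frozenset(
                               n for n in DESCRIPTOR_NAMES
                               if _gold_has(gold, n)))
    matched = set()
    missed = set()
    for name in DESCRIPTOR_NAMES:
        state = _descriptor_state(system, gold, name)
        if state is True:
            matched.add(name)
        elif state is False:
            missed.add(name)
    if not missed:
        category = MatchCategory.FULL
    elif not matched:
        category = MatchCategory.NO_MATCH
    else:
        category = MatchCategory.PARTIAL
    return MatchResult(gold.frame_id, category, frozenset(matched), frozenset(missed))


def _gold_has(gold: MeasurementFrame, name: str) -> bool:
    if name == "temporality":
        return True
    v = gold.descriptor(name)
    return bool(v) if isinstance(v, list) else v is not None


def evaluate_matches(system: Sequence[MeasurementFrame],
                     gold: Sequence[MeasurementFrame]) -> list[MatchResult]:
    """One MatchResult per gold frame, via greedy alignment."""
    pairs, _, un_g = align_frames(system, gold)
    results = [classify_match(s, g) for s, g in pairs]
    results += [classify_match(None, g) for g in un_g]
    return results


def match_counts(results: Iterable[MatchResult]) -> dict[str, int]:
    out = {c.value: 0 for c in MatchCategory}
    for r in results:
        out[r.category.value] += 1
    return out


def combination_match_table(
    results: Sequence[MatchResult],
    combinations: Sequence[Sequence[str]],
) -> pd.DataFrame:
    """Counts/percentages of frames whose matched descriptors cover each
    combination; antitone in combination inclusion by construction."""
    total = len(results)
    rows = []
    for combo in combinations:
        cset = frozenset(combo)
        count = sum(1 for r in results if cset <= r.matched_descriptors)
        rows.append({
            "combination": "+".join(sorted(cset)) if cset else "(any)",
            "count": count,
            "percent": round(100.0 * count / total, 2) if total else 0.0,
        })
    return pd.DataFrame(rows)


def compare_pipelines(
    baseline: Sequence[MeasurementFrame],
    proposed: Sequence[MeasurementFrame],
    gold: Sequence[MeasurementFrame],
) -> pd.DataFrame:
    """Side-by-side per-descriptor metrics for two systems on the same gold."""
    rows = []
    for info in INFORMATION_TYPES:
        row = {"information_type": info}
        for name, frames in (("baseline", baseline), ("proposed", proposed)):
            m = metrics_from_counts(score_descriptor(frames, gold, info)).rounded()
            row[f"{name}_precision"] = m.precision
            row[f"{name}_recall"] = m.recall
            row[f"{name}_f_score"] = m.f_score
        rows.append(row)
    return pd.DataFrame(rows)
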