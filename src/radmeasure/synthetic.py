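"""Synthetic Findings-style reports with paired gold annotations.

Real radiology corpora are private, so this generator emulates the sentence
patterns the pipeline assumes — size expressions of 1-3 dimensions, current /
prior measurement pairs ("4 mm ... previously 7 mm"), image/series/segment
references, and entity modifiers drawn from the packaged lexicons — and emits
three mutually consistent gold views per corpus: measurement frames (JSONL),
standoff entity annotations (JSONL), and token-level BIO (TSV).

Surface-variant injection (benign typos) is the only source of
out-of-lexicon entity forms; it simulates the lexical variation that makes a
trainable tagger worth having over dictionary lookup. All randomness flows
from one integer-seeded ``random.Random``, so corpora are reproducible
across platforms.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .corpus import StandoffSentence, write_bio_tsv, write_standoff
from .frames import write_frames
from .lexicons import Lexicons, load_lexicons
from .ner import spans_to_bio
from .pos import tokenize_and_pos
from .types import EntityType, MeasurementFrame, Report, Temporality


def _check_dist(d: dict, name: str) -> None:
    if not d:
        raise ValueError(f"{name}: empty distribution")
    if any(p < 0 for p in d.values()) or abs(sum(d.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities must be >= 0 and sum to 1")


@dataclass
class GeneratorConfig:
    seed: int = 7
    n_reports: int = 100
    sentences_per_report: tuple[int, int] = (3, 6)  # measurement sentences, inclusive
    plain_sentences_per_report: tuple[int, int] = (1, 3)
    measurements_per_sentence: dict = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    prior_pair_probability: float = 0.3
    dimension_count: dict = field(default_factory=lambda: {1: 0.6, 2: 0.25, 3: 0.15})
    unit_mix: dict = field(default_factory=lambda: {"mm": 0.7, "cm": 0.3})
    variant_rate: float = 0.1
    anatomy_path: Optional[str] = None
    observations_path: Optional[str] = None
    descriptors_path: Optional[str] = None

    def validate(self) -> None:
        _check_dist(self.measurements_per_sentence, "measurements_per_sentence")
        _check_dist(self.dimension_count, "dimension_count")
        _check_dist(self.unit_mix, "unit_mix")
        for p in (self.prior_pair_probability, self.variant_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")


@dataclass
class GoldCorpus:
    reports: list[Report]
    gold_frames: list[MeasurementFrame]
    standoff: list[StandoffSentence]

    def write(self, outdir: "str | Path") -> dict:
        outdir = Path(outdir)
        (outdir / "reports").mkdir(parents=True, exist_ok=True)
        manifest = {}
        for rep in self.reports:
            path = outdir / "reports" / f"{rep.doc_id}.txt"
            path.write_text(rep.raw_text, encoding="utf-8")
            manifest[rep.doc_id] = str(path)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8")
        write_frames(self.gold_frames, outdir / "gold_frames.jsonl")
        write_standoff(self.standoff, outdir / "standoff.jsonl")
        sequences = []
        for rec in self.standoff:
            tokens = tokenize_and_pos(rec.text)
            spans = [(e["start"], e["end"], e["label"]) for e in rec.entities]
            sequences.append((tokens, spans_to_bio(tokens, spans)))
        write_bio_tsv(sequences, outdir / "gold_bio.tsv")
        return manifest


def _pick(rng: random.Random, dist: dict):
    r = rng.random()
    acc = 0.0
    items = sorted(dist.items(), key=lambda kv: str(kv[0]))
    for value, p in items:
        acc += p
        if r < acc:
            return value
    return items[-1][0]


def _typo(rng: random.Random, word: str) -> str:
    if len(word) < 4:
        return word + word[-1]
    i = rng.randrange(1, len(word) - 2)
    if rng.random() < 0.5:
        return word[:i] + word[i + 1:]  # drop a letter
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]  # swap neighbors


class _SentenceBuilder:
    """Accumulates text while recording entity spans and measurement facts."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.entities: list[dict] = []

    def add(self, text: str) -> tuple[int, int]:
        span = (self.length, self.length + len(text))
        self.parts.append(text)
        self.length += len(text)
        return span

    def add_entity(self, surface: str, label: str) -> tuple[int, int]:
        span = self.add(surface)
        self.entities.append({"start": span[0], "end": span[1], "label": label})
        return span

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _size_expr(rng: random.Random, config: GeneratorConfig) -> tuple[str, list[float], str]:
    n_dims = _pick(rng, config.dimension_count)
    unit = _pick(rng, config.unit_mix)
    values = []
    for _ in range(n_dims):
        if unit == "mm":
            v = float(rng.randrange(1, 30))
        else:
            v = round(rng.randrange(5, 80) / 10.0, 1)
        values.append(v)
    fmt = lambda v: ("%g" % v)
    if n_dims == 1:
        return f"{fmt(values[0])} {unit}", values, unit
    return " x ".join(fmt(v) for v in values) + f" {unit}", values, unit


def _entity_surface(rng: random.Random, term: str, rate: float) -> str:
    if rng.random() >= rate:
        return term
    words = term.split()
    i = rng.randrange(len(words))
    words[i] = _typo(rng, words[i])
    return " ".join(words)


@dataclass
class _MeasurementPlan:
    values: list[float]
    unit: str
    span: tuple[int, int]
    surface: str
    temporality: Temporality
    anatomical_entity: list[str] = field(default_factory=list)
    imaging_observation: list[str] = field(default_factory=list)
    radlex_descriptor: list[str] = field(default_factory=list)
    image_number: Optional[int] = None
    series_number: Optional[int] = None
    segment: Optional[int] = None


def generate_sentence(
    rng: random.Random,
    config: GeneratorConfig,
    lexicons: Lexicons,
    doc_id: str = "synthetic",
    sent_id: int = 0,
) -> tuple[str, list[MeasurementFrame], list[dict]]:
    """One Findings sentence plus its gold frames and standoff entities.

    Four template families are drawn from: observation-first, measurement-
    first, series-prefix (possibly enumerating several measurements), and a
    segment template; current measurements optionally carry a prior
    parenthetical ("(image N, previously M mm)").
    """
    anatomy = sorted(lexicons.anatomy)
    observations = sorted(t for t in lexicons.observations if t != "enhancing")
    descriptors = sorted(lexicons.descriptors)
    b = _SentenceBuilder()
    plans: list[_MeasurementPlan] = []
    n_meas_groups = _pick(rng, config.measurements_per_sentence)
    template = rng.choice(["obs_first", "meas_first", "series_prefix", "segment"])
    series = rng.randrange(1, 20) if rng.random() < 0.6 else None

    def emit_pair(ae_term: str, io_term: str, rd_term: Optional[str],
                  segment_no: Optional[int], lead_rd_for_all: bool) -> None:
        """Emit 'SIZE AE IO (image N, previously SIZE2)'-style measurement."""
        image = rng.randrange(10, 400) if rng.random() < 0.8 else None
        expr, values, unit = _size_expr(rng, config)
        span = b.add(expr)
        cur = _MeasurementPlan(values, unit, span, expr, Temporality.CURRENT,
                               image_number=image, series_number=series,
                               segment=segment_no)
        b.add(" ")
        ae_surface = _entity_surface(rng, ae_term, config.variant_rate)
        b.add_entity(ae_surface, EntityType.ANATOMICAL_ENTITY.value)
        cur.anatomical_entity.append(ae_surface)
        b.add(" ")
        io_surface = _entity_surface(rng, io_term, config.variant_rate)
        b.add_entity(io_surface, EntityType.IMAGING_OBSERVATION.value)
        cur.imaging_observation.append(io_surface)
        if rd_term is not None:
            cur.radlex_descriptor.append(rd_term)
        prior = None
        has_prior = rng.random() < config.prior_pair_probability
        if image is not None or has_prior:
            b.add(" (")
            if image is not None:
                b.add(f"image {image}")
            if has_prior:
                if image is not None:
                    b.add(", " if rng.random() < 0.8 else "; ")
                b.add("previously ")
                pexpr, pvalues, punit = _size_expr(rng, config)
                pspan = b.add(pexpr)
                prior = _MeasurementPlan(
                    pvalues, punit, pspan, pexpr, Temporality.PRIOR,
                    anatomical_entity=list(cur.anatomical_entity),
                    imaging_observation=list(cur.imaging_observation),
                    radlex_descriptor=list(cur.radlex_descriptor),
                    image_number=image, series_number=series, segment=segment_no)
            b.add(")")
        plans.append(cur)
        if prior is not None:
            plans.append(prior)

    segment_no = None
    if template == "obs_first":
        rd = rng.choice(descriptors) if rng.random() < 0.5 else None
        io = rng.choice(observations)
        ae = rng.choice(anatomy)
        b.add("There is a ")
        if rd is not None:
            rd_surface = _entity_surface(rng, rd, config.variant_rate)
            b.add_entity(rd_surface, EntityType.RADLEX_DESCRIPTOR.value)
            b.add(" ")
        io_surface = _entity_surface(rng, io, config.variant_rate)
        b.add_entity(io_surface, EntityType.IMAGING_OBSERVATION.value)
        b.add(" in the ")
        ae_surface = _entity_surface(rng, ae, config.variant_rate)
        b.add_entity(ae_surface, EntityType.ANATOMICAL_ENTITY.value)
        b.add(" measuring ")
        image = rng.randrange(10, 400) if rng.random() < 0.7 else None
        expr, values, unit = _size_expr(rng, config)
        span = b.add(expr)
        cur = _MeasurementPlan(values, unit, span, expr, Temporality.CURRENT,
                               anatomical_entity=[ae_surface],
                               imaging_observation=[io_surface],
                               radlex_descriptor=[rd_surface] if rd is not None else [],
                               image_number=image, series_number=series)
        plans.append(cur)
        tail_bits = []
        if series is not None:
            tail_bits.append(f"series {series}")
        if image is not None:
            tail_bits.append(f"image {image}")
        if tail_bits:
            b.add(" (" + ", ".join(tail_bits) + ")")
        if rng.random() < config.prior_pair_probability:
            b.add(", previously ")
            pexpr, pvalues, punit = _size_expr(rng, config)
            pspan = b.add(pexpr)
            plans.append(_MeasurementPlan(
                pvalues, punit, pspan, pexpr, Temporality.PRIOR,
                anatomical_entity=[ae_surface], imaging_observation=[io_surface],
                radlex_descriptor=list(cur.radlex_descriptor),
                image_number=image, series_number=series))
    elif template == "segment":
        segment_no = rng.randrange(1, 9)
        b.add(f"Segment {segment_no} ")
        io = rng.choice(observations)
        io_surface = _entity_surface(rng, io, config.variant_rate)
        b.add_entity(io_surface, EntityType.IMAGING_OBSERVATION.value)
        b.add(" measures ")
        image = rng.randrange(10, 400) if rng.random() < 0.7 else None
        expr, values, unit = _size_expr(rng, config)
        span = b.add(expr)
        cur = _MeasurementPlan(values, unit, span, expr, Temporality.CURRENT,
                               imaging_observation=[io_surface],
                               image_number=image, series_number=series,
                               segment=segment_no)
        plans.append(cur)
        bits = []
        if image is not None:
            bits.append(f"image {image}")
        if series is not None:
            bits.append(f"series {series}")
        if bits:
            b.add(" (" + ", ".join(bits) + ")")
        if rng.random() < config.prior_pair_probability:
            b.add(", previously ")
            pexpr, pvalues, punit = _size_expr(rng, config)
            pspan = b.add(pexpr)
            plans.append(_MeasurementPlan(
                pvalues, punit, pspan, pexpr, Temporality.PRIOR,
                imaging_observation=[io_surface], image_number=image,
                series_number=series, segment=segment_no))
    else:
        lead_rd = None
        if template == "series_prefix" and series is None:
            series = rng.randrange(1, 20)
        if template == "series_prefix":
            b.add(f"On series {series}, ")
            if rng.random() < 0.6:
                lead_rd = rng.choice(descriptors)
                rd_surface = _entity_surface(rng, lead_rd, config.variant_rate)
                b.add_entity(rd_surface, EntityType.RADLEX_DESCRIPTOR.value)
                b.add(" ")
                lead_rd = rd_surface
            b.add("for example ")
        for k in range(n_meas_groups):
            if k > 0:
                b.add(", ")
            io = rng.choice(observations)
            ae = rng.choice(anatomy)
            rd = lead_rd if (lead_rd is not None and k == 0) else None
            emit_pair(ae, io, rd, segment_no, lead_rd_for_all=False)
    b.add(".")

    text = b.text
    gold: list[MeasurementFrame] = []
    for i, p in enumerate(plans):
        gold.append(MeasurementFrame(
            frame_id=f"{doc_id}:{sent_id}:{i}",
            doc_id=doc_id, sentence_id=sent_id,
            value=p.values[0], unit=p.unit, dimensions=p.values,
            measurement_span=p.span, surface=p.surface,
            temporality=p.temporality.value,
            anatomical_entity=p.anatomical_entity,
            imaging_observation=p.imaging_observation,
            radlex_descriptor=p.radlex_descriptor,
            image_number=p.image_number, series_number=p.series_number,
            segment=p.segment,
        ))
    return text, gold, b.entities


_PLAIN_SENTENCES = [
    "The visualized osseous structures are unremarkable.",
    "No acute intracranial hemorrhage is identified.",
    "The remaining parenchyma is normal in appearance.",
    "No new focus of abnormal signal is seen.",
    "Imaging was performed without intravenous contrast.",
    "There is no evidence of metastatic disease.",
]

_HISTORIES = [
    "Follow-up of known malignancy.",
    "Restaging examination.",
    "Evaluation of treatment response.",
    "Surveillance imaging.",
]


def generate_corpus(config: GeneratorConfig, outdir: "str | Path | None" = None
                    ) -> GoldCorpus:
    """Generate ``config.n_reports`` reports with consistent gold views.

    Reports carry conventional section headers; every measurement sentence in
    the Findings body has gold frames and standoff entities. When ``outdir``
    is given, report files, a manifest, gold frames JSONL, standoff JSONL and
    a BIO TSV are written there.
    """
    config.validate()
    lexicons = load_lexicons(config.anatomy_path, config.observations_path,
                             config.descriptors_path)
    rng = random.Random(config.seed)
    reports: list[Report] = []
    frames: list[MeasurementFrame] = []
    standoff: list[StandoffSentence] = []
    for r in range(config.n_reports):
        doc_id = f"synth-{r:04d}"
        n_meas = rng.randint(*config.sentences_per_report)
        n_plain = rng.randint(*config.plain_sentences_per_report)
        slots = [True] * n_meas + [False] * n_plain
        rng.shuffle(slots)
        sentences: list[str] = []
        for sent_id, is_meas in enumerate(slots):
            if is_meas:
                text, gold, entities = generate_sentence(
                    rng, config, lexicons, doc_id=doc_id, sent_id=sent_id)
                frames.extend(gold)
                standoff.append(StandoffSentence(doc_id, sent_id, text, entities))
            else:
                text = rng.choice(_PLAIN_SENTENCES)
            sentences.append(text)
        raw = (
            f"CLINICAL HISTORY: {rng.choice(_HISTORIES)}\n"
            f"TECHNIQUE: Multiplanar imaging was obtained.\n"
            f"FINDINGS: {' '.join(sentences)}\n"
            f"IMPRESSION: Findings as described above.\n"
        )
        from .preprocessing import make_report

        reports.append(make_report(doc_id, raw))
    corpus = GoldCorpus(reports=reports, gold_frames=frames, standoff=standoff)
    if outdir is not None:
        corpus.write(outdir)
    return corpus


def corrupt_for_light_annotation(
    standoff: list[StandoffSentence],
    drop_rate: float,
    rng: random.Random,
    shift_rate: float = 0.1,
) -> list[StandoffSentence]:
    """Degrade gold standoff to emulate uncorrected dictionary pre-annotation.

    Each entity is dropped with probability ``drop_rate``; survivors have a
    boundary shrunk by one character with probability ``shift_rate``. Used to
    study CRF robustness to noisy (pre-correction) training gold.
    """
    if not 0.0 <= drop_rate <= 1.0:
        raise ValueError("drop_rate must lie in [0, 1]")
    out = []
    for rec in standoff:
        kept = []
        for ent in rec.entities:
            if rng.random() < drop_rate:
                continue
            ent = dict(ent)
            if rng.random() < shift_rate and ent["end"] - ent["start"] > 2:
                if rng.random() < 0.5:
                    ent["start"] += 1
                else:
                    ent["end"] -= 1
            kept.append(ent)
        out.append(StandoffSentence(rec.doc_id, rec.sent_id, rec.text, kept))
    return out
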