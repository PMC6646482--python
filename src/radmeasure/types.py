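"""Domain objects shared across the extraction pipeline.

Span conventions: section and sentence spans index the report's raw text;
every other span (measurements, scan references, entities, sub-sentences)
indexes the text of its parent sentence. All spans are 0-based half-open
``(start, end)`` pairs over the decoded unicode string.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from typing import Optional


class SectionName(str, enum.Enum):
    COMPARISON = "COMPARISON"
    TECHNIQUE = "TECHNIQUE"
    CLINICAL_HISTORY = "CLINICAL_HISTORY"
    FINDINGS = "FINDINGS"
    CONCLUSIONS = "CONCLUSIONS"
    OTHER = "OTHER"


class Temporality(str, enum.Enum):
    CURRENT = "CURRENT"
    PRIOR = "PRIOR"


class ScanRefKind(str, enum.Enum):
    IMAGE = "IMAGE"
    SERIES = "SERIES"
    SEGMENT = "SEGMENT"


class EntityType(str, enum.Enum):
    ANATOMICAL_ENTITY = "ANATOMICAL_ENTITY"
    IMAGING_OBSERVATION = "IMAGING_OBSERVATION"
    RADLEX_DESCRIPTOR = "RADLEX_DESCRIPTOR"


@dataclass
class Section:
    name: SectionName
    start: int
    end: int
    header_span: Optional[tuple[int, int]] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Sentence:
    sent_id: int
    start: int
    end: int
    text: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Report:
    doc_id: str
    raw_text: str
    sections: list[Section] = field(default_factory=list)


@dataclass
class Dimension:
    """One measured axis: a positive number with a length unit."""

    value: float
    unit: str  # "mm" or "cm", normalized
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"dimension value must be positive, got {self.value}")
        if self.unit not in ("mm", "cm"):
            raise ValueError(f"unsupported unit {self.unit!r}")


@dataclass
class MeasurementMention:
    """A size expression of 1-3 dimensions, e.g. '4 mm' or '1.2 x 3.4 x 2.0 cm'."""

    mention_id: int
    dimensions: list[Dimension]
    start: int
    end: int
    surface: str
    temporality: Optional[Temporality] = None
    cue_span: Optional[tuple[int, int]] = None  # span of the governing prior cue, if any

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def value(self) -> float:
        """Leading dimension value (the frame's scalar size)."""
        return self.dimensions[0].value

    @property
    def unit(self) -> str:
        return self.dimensions[0].unit


@dataclass
class SubSentence:
    """A contiguous sentence fragment owning exactly one measurement."""

    sent_id: int
    start: int
    end: int
    measurement: MeasurementMention

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ScanReference:
    kind: ScanRefKind
    number: int
    start: int
    end: int
    surface: str = ""

    def __post_init__(self) -> None:
        if self.number < 0:
            raise ValueError("scan reference number must be >= 0")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class EntityMention:
    type: EntityType
    start: int
    end: int
    surface: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Token:
    surface: str
    start: int
    end: int
    pos: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# Descriptor slot names, in the order the system reports them.
DESCRIPTOR_NAMES = (
    "temporality",
    "anatomical_entity",
    "imaging_observation",
    "radlex_descriptor",
    "image_number",
    "series_number",
    "segment",
)


@dataclass
class MeasurementFrame:
    """Structured output: one measurement plus its seven descriptor slots."""

    frame_id: str
    doc_id: str
    sentence_id: int
    value: float
    unit: str
    dimensions: list[float]
    measurement_span: tuple[int, int]
    surface: str
    temporality: str = Temporality.CURRENT.value
    anatomical_entity: list[str] = field(default_factory=list)
    imaging_observation: list[str] = field(default_factory=list)
    radlex_descriptor: list[str] = field(default_factory=list)
    image_number: Optional[int] = None
    series_number: Optional[int] = None
    segment: Optional[int] = None

    def descriptor(self, name: str):
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["measurement_span"] = list(self.measurement_span)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementFrame":
        d = dict(d)
        d.pop("schema", None)
        d["measurement_span"] = tuple(d["measurement_span"])
        return cls(**d)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsRow:
    """Precision/recall/F as percentages; None marks an undefined metric."""

    information_type: str
    precision: Optional[float]
    recall: Optional[float]
    f_score: Optional[float]

    def rounded(self) -> "MetricsRow":
        r = lambda v: None if v is None else round(v, 2)
        return MetricsRow(self.information_type, r(self.precision), r(self.recall), r(self.f_score))


class MatchCategory(str, enum.Enum):
    FULL = "FULL"
    PARTIAL = "PARTIAL"
    NO_MATCH = "NO_MATCH"


@dataclass
class MatchResult:
    frame_id: str
    category: MatchCategory
    matched_descriptors: frozenset
    missed_descriptors: frozenset
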