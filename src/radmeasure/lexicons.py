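"""Built-in term lists for anatomical entities, imaging observations and
RadLex-style descriptors.

The study-grade dictionaries behind such systems are institution-curated and
not redistributable, so the package ships small, user-replaceable word lists
that cover common CT/MR/mammography vocabulary. They drive the dictionary
baseline tagger, the CRF dictionary-map features, and the synthetic corpus
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .types import EntityType

_DATA_FILES = {
    EntityType.ANATOMICAL_ENTITY: "anatomy.txt",
    EntityType.IMAGING_OBSERVATION: "observations.txt",
    EntityType.RADLEX_DESCRIPTOR: "descriptors.txt",
}


_PUNCT_TABLE = str.maketrans("", "", "".join(chr(c) for c in range(33, 127)
                                             if not chr(c).isalnum() and chr(c) != " "))


def _expand(terms: set[str]) -> frozenset[str]:
    """Add punctuation-stripped variants ('ill-defined' -> 'illdefined') so
    terms still match after post-tagging punctuation removal."""
    out = set(terms)
    for t in terms:
        stripped = t.translate(_PUNCT_TABLE)
        if stripped and stripped != t:
            out.add(stripped)
    return frozenset(out)


def _read_terms(text: str) -> frozenset[str]:
    terms = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            terms.add(line)
    return _expand(terms)


@dataclass(frozen=True)
class Lexicons:
    """Three case-insensitive term sets keyed by entity type."""

    anatomy: frozenset[str]
    observations: frozenset[str]
    descriptors: frozenset[str]

    def by_type(self, etype: EntityType) -> frozenset[str]:
        return {
            EntityType.ANATOMICAL_ENTITY: self.anatomy,
            EntityType.IMAGING_OBSERVATION: self.observations,
            EntityType.RADLEX_DESCRIPTOR: self.descriptors,
        }[etype]

    @property
    def max_term_tokens(self) -> int:
        return max(
            len(t.split()) for s in (self.anatomy, self.observations, self.descriptors) for t in s
        )

    def contains(self, etype: EntityType, term: str) -> bool:
        """Membership with naive singular fallback ('nodules' -> 'nodule')."""
        term = " ".join(term.lower().split())
        lex = self.by_type(etype)
        if term in lex:
            return True
        if term.endswith("s") and term[:-1] in lex:
            return True
        return False


def load_lexicons(
    anatomy_path: "str | Path | None" = None,
    observations_path: "str | Path | None" = None,
    descriptors_path: "str | Path | None" = None,
) -> Lexicons:
    """Load lexicons from paths, falling back to the packaged word lists."""

    def load(path, etype):
        if path is not None:
            return _read_terms(Path(path).read_text(encoding="utf-8"))
        ref = resources.files("radmeasure.data").joinpath(_DATA_FILES[etype])
        return _read_terms(ref.read_text(encoding="utf-8"))

    return Lexicons(
        anatomy=load(anatomy_path, EntityType.ANATOMICAL_ENTITY),
        observations=load(observations_path, EntityType.IMAGING_OBSERVATION),
        descriptors=load(descriptors_path, EntityType.RADLEX_DESCRIPTOR),
    )


def lexicons_from_terms(
    anatomy: Iterable[str], observations: Iterable[str], descriptors: Iterable[str]
) -> Lexicons:
    return Lexicons(
        anatomy=_expand({t.lower() for t in anatomy}),
        observations=_expand({t.lower() for t in observations}),
        descriptors=_expand({t.lower() for t in descriptors}),
    )
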