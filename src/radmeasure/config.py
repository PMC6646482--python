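"""Pipeline configuration: one validated JSON file drives every subcommand.

Unknown keys are rejected so typos fail loudly before any processing. CLI
flags override config values; the effective configuration is echoed to the
log for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from .lexicons import Lexicons, load_lexicons
from .measurements import DEFAULT_CURRENT_CUES, DEFAULT_PRIOR_CUES
from .preprocessing import DEFAULT_HEADER_PATTERNS


class ConfigError(ValueError):
    pass


class CRFOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    c2: float = 1.0
    max_iterations: int = 100
    include_rule_labels: bool = False


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    header_patterns: dict[str, list[str]] = DEFAULT_HEADER_PATTERNS
    prior_cues: list[str] = list(DEFAULT_PRIOR_CUES)
    current_cues: list[str] = list(DEFAULT_CURRENT_CUES)
    anatomy_lexicon: Optional[str] = None
    observations_lexicon: Optional[str] = None
    descriptors_lexicon: Optional[str] = None
    ner_mode: Literal["dictionary", "crf"] = "dictionary"
    crf: CRFOptions = CRFOptions()
    seed: int = 7
    log_level: str = "INFO"

    def load_lexicons(self) -> Lexicons:
        return load_lexicons(self.anatomy_lexicon, self.observations_lexicon,
                             self.descriptors_lexicon)


def load_config(path: "str | Path | None") -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
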