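"""Named entity tagging of measurement-bearing text.

Two taggers share one tokenizer and one lexicon set:

* a dictionary baseline — greedy leftmost-longest lookup of lexicon terms,
  also used to pre-annotate corpora for light annotation; and
* a trainable linear-chain CRF over token features (lowercased form, POS tag,
  dictionary-map flags, affixes, digit flag, and a +/-2 context window — no
  chunk or parse features).

Both emit typed entity spans for anatomical entities, imaging observations
and RadLex-style descriptors via the BIO scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crf import CRFError, LinearChainCRF
from .lexicons import Lexicons
from .pos import tokenize_and_pos
from .types import EntityMention, EntityType, Token

TEMPLATE_VERSION = "tpl-1"

ENTITY_LABELS = tuple(t.value for t in EntityType)
RULE_LABELS = ("MEASUREMENT", "IMAGE", "SERIES", "SEGMENT", "TEMPORALITY")

_FLAG_NAMES = {
    EntityType.ANATOMICAL_ENTITY: "is_anatomy",
    EntityType.IMAGING_OBSERVATION: "is_observation",
    EntityType.RADLEX_DESCRIPTOR: "is_descriptor",
}


def bio_label_set(entity_types=ENTITY_LABELS, include_rule_labels: bool = False) -> list[str]:
    types = list(entity_types) + (list(RULE_LABELS) if include_rule_labels else [])
    labels = ["O"]
    for t in types:
        labels += [f"B-{t}", f"I-{t}"]
    return labels


# -- dictionary matching -----------------------------------------------------

def _ngram_matches(tokens: list[Token], lexicons: Lexicons, etype: EntityType,
                   max_n: int | None = None) -> list[tuple[int, int]]:
    """All (i, j) token ranges whose words form a lexicon term (overlap allowed)."""
    max_n = max_n or lexicons.max_term_tokens
    out = []
    for i in range(len(tokens)):
        for n in range(1, max_n + 1):
            j = i + n
            if j > len(tokens):
                break
            phrase = " ".join(t.surface for t in tokens[i:j])
            if lexicons.contains(etype, phrase):
                out.append((i, j))
    return out


def dictionary_flags(tokens: list[Token], lexicons: Lexicons) -> list[dict[str, bool]]:
    """Per-token lexicon membership flags (token lies inside some lexicon term)."""
    flags = [dict.fromkeys(_FLAG_NAMES.values(), False) for _ in tokens]
    for etype, flag in _FLAG_NAMES.items():
        for i, j in _ngram_matches(tokens, lexicons, etype):
            for k in range(i, j):
                flags[k][flag] = True
    return flags


def dictionary_tag(tokens: list[Token], lexicons: Lexicons, text: str | None = None
                   ) -> list[EntityMention]:
    """Greedy leftmost-longest, case-insensitive lexicon tagging.

    At each position the longest matching term wins; at equal length the tie
    breaks anatomical entity > imaging observation > RadLex descriptor.
    Output spans never overlap. Serves both as the baseline system and as the
    pre-annotator for light annotation.
    """
    entities: list[EntityMention] = []
    i = 0
    order = (EntityType.ANATOMICAL_ENTITY, EntityType.IMAGING_OBSERVATION,
             EntityType.RADLEX_DESCRIPTOR)
    max_n = lexicons.max_term_tokens
    while i < len(tokens):
        best: tuple[int, EntityType] | None = None
        for n in range(max_n, 0, -1):
            j = i + n
            if j > len(tokens):
                continue
            phrase = " ".join(t.surface for t in tokens[i:j])
            for etype in order:
                if lexicons.contains(etype, phrase):
                    best = (j, etype)
                    break
            if best:
                break
        if best is None:
            i += 1
            continue
        j, etype = best
        start, end = tokens[i].start, tokens[j - 1].end
        surface = text[start:end] if text is not None else " ".join(
            t.surface for t in tokens[i:j])
        entities.append(EntityMention(etype, start, end, surface))
        i = j
    return entities


# -- features ----------------------------------------------------------------

def featurize(tokens: list[Token], lexicons: Lexicons) -> list[dict]:
    """One sparse feature dict per token; window features for +/-2 neighbors.

    Boundary positions get BOS/EOS sentinels instead of missing-context
    features, so feature names are stable across train and predict.
    """
    flags = dictionary_flags(tokens, lexicons)
    n = len(tokens)
    base: list[dict] = []
    for t, fl in zip(tokens, flags):
        low = t.surface.lower()
        f = {
            "bias": 1.0,
            f"w={low}": 1.0,
            f"pos={t.pos}": 1.0,
            f"suf3={low[-3:]}": 1.0,
            f"pre3={low[:3]}": 1.0,
        }
        if low.replace(".", "", 1).isdigit():
            f["is_digit"] = 1.0
        for name, on in fl.items():
            if on:
                f[name] = 1.0
        base.append(f)
    out: list[dict] = []
    for i in range(n):
        f = dict(base[i])
        for d in (-2, -1, 1, 2):
            j = i + d
            if 0 <= j < n:
                t = tokens[j]
                low = t.surface.lower()
                f[f"{d}:w={low}"] = 1.0
                f[f"{d}:pos={t.pos}"] = 1.0
                for name, on in flags[j].items():
                    if on:
                        f[f"{d}:{name}"] = 1.0
            else:
                f[f"{d}:{'BOS' if d < 0 else 'EOS'}"] = 1.0
        out.append(f)
    return out


# -- BIO handling ------------------------------------------------------------

def repair_bio(labels: list[str]) -> list[str]:
    """Rewrite headless I-X to B-X so every sequence is BIO-valid."""
    out = []
    prev = "O"
    for lab in labels:
        if lab.startswith("I-"):
            t = lab[2:]
            if prev not in (f"B-{t}", f"I-{t}"):
                lab = f"B-{t}"
        out.append(lab)
        prev = lab
    return out


def is_valid_bio(labels: list[str]) -> bool:
    prev = "O"
    for lab in labels:
        if lab.startswith("I-") and prev not in (f"B-{lab[2:]}", f"I-{lab[2:]}"):
            return False
        prev = lab
    return True


def labels_to_entities(tokens: list[Token], labels: list[str], text: str | None = None
                       ) -> list[EntityMention]:
    """Collapse maximal B-I runs into typed entity mentions (entity labels only)."""
    if len(tokens) != len(labels):
        raise ValueError("token/label length mismatch")
    entities: list[EntityMention] = []
    i = 0
    while i < len(labels):
        lab = labels[i]
        if not lab.startswith("B-"):
            i += 1
            continue
        t = lab[2:]
        j = i + 1
        while j < len(labels) and labels[j] == f"I-{t}":
            j += 1
        if t in ENTITY_LABELS:
            start, end = tokens[i].start, tokens[j - 1].end
            surface = text[start:end] if text is not None else " ".join(
                tok.surface for tok in tokens[i:j])
            entities.append(EntityMention(EntityType(t), start, end, surface))
        i = j
    return entities


def spans_to_bio(tokens: list[Token], spans: list[tuple[int, int, str]]) -> list[str]:
    """Project (start, end, type) character spans onto token BIO labels."""
    labels = ["O"] * len(tokens)
    for start, end, t in sorted(spans):
        inside = [k for k, tok in enumerate(tokens) if tok.start < end and tok.end > start]
        for pos, k in enumerate(inside):
            if labels[k] != "O":
                continue
            labels[k] = ("B-" if pos == 0 or labels[inside[pos - 1]] == "O" else "I-") + t
    return repair_bio(labels)


# -- CRF wrappers ------------------------------------------------------------

def train_crf(
    corpus: list[tuple[list[dict], list[str]]],
    label_set: list[str] | None = None,
    c2: float = 1.0,
    max_iterations: int = 100,
) -> LinearChainCRF:
    """Train the sequence model on (feature sequence, BIO label sequence) pairs."""
    if not corpus:
        raise CRFError("empty training corpus")
    x_seqs = [x for x, _ in corpus]
    y_seqs = [y for _, y in corpus]
    model = LinearChainCRF(c2=c2, max_iterations=max_iterations,
                           template_version=TEMPLATE_VERSION)
    model.fit(x_seqs, y_seqs, label_set=label_set)
    return model


def predict_labels(model: LinearChainCRF, features: list[dict],
                   template_version: str = TEMPLATE_VERSION) -> list[str]:
    """Predict one BIO label per token, repaired to validity."""
    if model.template_version != template_version:
        raise CRFError(
            f"feature template mismatch: model={model.template_version!r}, "
            f"features={template_version!r}"
        )
    return repair_bio(model.predict(features))


@dataclass
class TransitionMatrix:
    """Label-to-label transition scores learned by the CRF.

    ``scores`` holds the raw (unnormalized) linear-chain transition
    parameters; ``normalized()`` offers a softmax view per source label for
    visualization, clearly a rescaling rather than a true conditional
    probability.
    """

    labels: list[str]
    scores: np.ndarray

    def score(self, src: str, dst: str) -> float:
        return float(self.scores[self.labels.index(src), self.labels.index(dst)])

    def normalized(self) -> np.ndarray:
        z = self.scores - self.scores.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=self.labels, columns=self.labels)


def extract_transition_scores(model: LinearChainCRF) -> TransitionMatrix:
    return TransitionMatrix(labels=list(model.labels), scores=model.transition_matrix())


__all__ = [
    "TEMPLATE_VERSION", "ENTITY_LABELS", "RULE_LABELS", "bio_label_set",
    "dictionary_flags", "dictionary_tag", "featurize", "repair_bio",
    "is_valid_bio", "labels_to_entities", "spans_to_bio", "train_crf",
    "predict_labels", "TransitionMatrix", "extract_transition_scores",
    "tokenize_and_pos",
]
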