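"""Shared fixtures: worked-example sentence, lexicons, synthetic corpus, and a
session-trained CRF used by the recovery and transition tests."""

from __future__ import annotations

import re

import pytest
from hypothesis import settings

from radmeasure import MeasurementFrame, load_lexicons
from radmeasure import corpus as corpus_mod
from radmeasure.ner import bio_label_set, train_crf
from radmeasure.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# The canonical multi-nodule Findings sentence: five current measurements,
# each with a prior parenthetical, sharing one leading series reference.
DISCUSSION_SENTENCE = (
    "reduced size of scattered enhancing nodules on series 11, for example "
    "4 mm left frontal nodule (image 127, previously 7 mm), "
    "4 mm right frontal nodule (image 124, previously 9 mm), "
    "3 mm right frontal nodule (image 114; previously 7 mm), "
    "2 mm lateral right frontal nodule (image 118, previously 5 mm), "
    "2 mm left cerebellar nodule (image 53, previously 6 mm)."
)

DISCUSSION_AES = ["left frontal", "right frontal", "right frontal",
                  "lateral right frontal", "left cerebellar"]
DISCUSSION_IMAGES = [127, 124, 114, 118, 53]


def make_discussion_gold(doc_id: str = "disc") -> list[MeasurementFrame]:
    """Gold frames for the worked example: the sentence-initial modifiers
    'scattered' and 'enhancing' are assigned to all ten frames."""
    spans = [(m.start(), m.end(), float(m.group(1)))
             for m in re.finditer(r"(\d+) mm", DISCUSSION_SENTENCE)]
    gold = []
    for i, (s, e, v) in enumerate(spans):
        pair = i // 2
        gold.append(MeasurementFrame(
            frame_id=f"gold:{i}", doc_id=doc_id, sentence_id=0,
            value=v, unit="mm", dimensions=[v], measurement_span=(s, e),
            surface=DISCUSSION_SENTENCE[s:e],
            temporality="CURRENT" if i % 2 == 0 else "PRIOR",
            anatomical_entity=[DISCUSSION_AES[pair]],
            imaging_observation=["enhancing", "nodule"],
            radlex_descriptor=["scattered"],
            image_number=DISCUSSION_IMAGES[pair], series_number=11))
    return gold


@pytest.fixture(scope="session")
def lexicons():
    return load_lexicons()


@pytest.fixture()
def discussion_sentence():
    return DISCUSSION_SENTENCE


@pytest.fixture()
def discussion_gold():
    return make_discussion_gold()


@pytest.fixture(scope="session")
def synth_corpus():
    corpus = generate_corpus(GeneratorConfig(seed=11, n_reports=230))
    assert len(corpus.standoff) >= 1000
    return corpus


@pytest.fixture(scope="session")
def prepared_split(synth_corpus, lexicons):
    """(train, test) feature/label sequences: 800 / 200 annotated sentences."""
    train = corpus_mod.prepare_sequences(
        synth_corpus.standoff[:800], lexicons, include_rule_labels=True)
    test = corpus_mod.prepare_sequences(
        synth_corpus.standoff[800:1000], lexicons, include_rule_labels=True)
    return train, test


@pytest.fixture(scope="session")
def trained_model(prepared_split):
    train, _ = prepared_split
    return train_crf([(p.features, p.labels) for p in train],
                     label_set=bio_label_set(include_rule_labels=True),
                     max_iterations=100)
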