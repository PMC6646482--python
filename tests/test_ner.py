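import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from radmeasure.crf import CRFError, LinearChainCRF
from radmeasure.lexicons import lexicons_from_terms
from radmeasure.ner import (
    bio_label_set,
    dictionary_tag,
    extract_transition_scores,
    featurize,
    is_valid_bio,
    labels_to_entities,
    predict_labels,
    repair_bio,
    spans_to_bio,
    train_crf,
)
from radmeasure.pos import tokenize_and_pos
from radmeasure.types import EntityType


class TestTokenizeAndPos:
    def test_spans_recover_surfaces(self):
        text = "4 mm left frontal nodule"
        tokens = tokenize_and_pos(text)
        assert [t.surface for t in tokens] == ["4", "mm", "left", "frontal", "nodule"]
        for t in tokens:
            assert text[t.start:t.end] == t.surface

    def test_empty_text(self):
        assert tokenize_and_pos("") == []

    def test_adjective_noun_categories(self):
        tokens = tokenize_and_pos("enhancing nodules")
        assert tokens[0].pos == "ADJ"
        assert tokens[1].pos == "NOUN"

    def test_numbers_and_punctuation(self):
        tokens = tokenize_and_pos("1.2 cm, stable.")
        assert tokens[0].pos == "NUM"
        assert tokens[2].pos == "PUNCT"


class TestFeaturize:
    def test_dictionary_flag_fires(self, lexicons):
        tokens = tokenize_and_pos("stable nodule")
        feats = featurize(tokens, lexicons)
        assert feats[1].get("is_observation") == 1.0

    def test_boundary_sentinels(self, lexicons):
        feats = featurize(tokenize_and_pos("nodule"), lexicons)
        assert feats[0].get("-1:BOS") == 1.0 and feats[0].get("1:EOS") == 1.0

    def test_digit_flag_without_lexicon_flags(self, lexicons):
        feats = featurize(tokenize_and_pos("127"), lexicons)
        assert feats[0].get("is_digit") == 1.0
        assert "is_anatomy" not in feats[0] and "is_observation" not in feats[0]


class TestDictionaryTag:
    def test_longest_match_beats_substring(self, lexicons):
        tokens = tokenize_and_pos("left frontal nodule")
        ents = dictionary_tag(tokens, lexicons, "left frontal nodule")
        assert [(e.type, e.surface) for e in ents] == [
            (EntityType.ANATOMICAL_ENTITY, "left frontal"),
            (EntityType.IMAGING_OBSERVATION, "nodule")]

    def test_out_of_lexicon_token_silent(self, lexicons):
        ents = dictionary_tag(tokenize_and_pos("xyzzy"), lexicons)
        assert ents == []

    def test_leftmost_longest_never_overlaps(self):
        lex = lexicons_from_terms(["upper lobe", "left upper lobe"],
                                  ["lobe mass", "mass"], [])
        text = "left upper lobe mass"
        ents = dictionary_tag(tokenize_and_pos(text), lex, text)
        assert [(e.surface, e.type) for e in ents] == [
            ("left upper lobe", EntityType.ANATOMICAL_ENTITY),
            ("mass", EntityType.IMAGING_OBSERVATION)]
        for a, b in zip(ents, ents[1:]):
            assert a.end <= b.start

    def test_plural_surface_matches_singular_term(self, lexicons):
        text = "scattered nodules"
        ents = dictionary_tag(tokenize_and_pos(text), lexicons, text)
        assert ("nodules", EntityType.IMAGING_OBSERVATION) in [
            (e.surface, e.type) for e in ents]


_LABELS = ["O", "B-ANATOMICAL_ENTITY", "I-ANATOMICAL_ENTITY",
           "B-IMAGING_OBSERVATION", "I-IMAGING_OBSERVATION"]


class TestBIO:
    @given(st.lists(st.sampled_from(_LABELS), max_size=20))
    def test_repair_always_yields_valid_bio(self, labels):
        assert is_valid_bio(repair_bio(labels))

    def test_repair_rewrites_headless_inside(self):
        assert repair_bio(["O", "I-ANATOMICAL_ENTITY"]) == ["O", "B-ANATOMICAL_ENTITY"]

    def test_labels_to_entities_runs(self):
        text = "left frontal nodule"
        tokens = tokenize_and_pos(text)
        labels = ["B-ANATOMICAL_ENTITY", "I-ANATOMICAL_ENTITY", "O"]
        (ent,) = labels_to_entities(tokens, labels, text)
        assert (ent.type, ent.surface) == (EntityType.ANATOMICAL_ENTITY, "left frontal")

    def test_all_outside_gives_no_entities(self):
        tokens = tokenize_and_pos("a b c")
        assert labels_to_entities(tokens, ["O"] * 3) == []

    def test_adjacent_begins_give_two_entities(self):
        tokens = tokenize_and_pos("liver nodule")
        labels = ["B-ANATOMICAL_ENTITY", "B-IMAGING_OBSERVATION"]
        ents = labels_to_entities(tokens, labels)
        assert [e.type for e in ents] == [EntityType.ANATOMICAL_ENTITY,
                                          EntityType.IMAGING_OBSERVATION]

    def test_spans_to_bio_projection(self):
        text = "left frontal nodule"
        tokens = tokenize_and_pos(text)
        labels = spans_to_bio(tokens, [(0, 12, "ANATOMICAL_ENTITY")])
        assert labels == ["B-ANATOMICAL_ENTITY", "I-ANATOMICAL_ENTITY", "O"]


def _toy_corpus(lexicons):
    seqs = []
    for text, spans in [
        ("stable nodule in the liver", [(7, 13, "IMAGING_OBSERVATION"),
                                        (21, 26, "ANATOMICAL_ENTITY")]),
        ("mass in the spleen", [(0, 4, "IMAGING_OBSERVATION"),
                                (12, 18, "ANATOMICAL_ENTITY")]),
    ]:
        tokens = tokenize_and_pos(text)
        seqs.append((featurize(tokens, lexicons), spans_to_bio(tokens, spans), tokens, text))
    return seqs


class TestCRFTraining:
    def test_memorizes_tiny_corpus(self, lexicons):
        seqs = _toy_corpus(lexicons)
        model = train_crf([(x, y) for x, y, _, _ in seqs], max_iterations=80)
        for x, y, _, _ in seqs:
            assert predict_labels(model, x) == y

    def test_single_sentence_trains(self, lexicons):
        (x, y, _, _) = _toy_corpus(lexicons)[0]
        model = train_crf([(x, y)], max_iterations=40)
        assert predict_labels(model, x) == y

    def test_empty_corpus_raises(self):
        with pytest.raises(CRFError):
            train_crf([])

    def test_undeclared_label_raises(self, lexicons):
        (x, y, _, _) = _toy_corpus(lexicons)[0]
        with pytest.raises(CRFError):
            train_crf([(x, y)], label_set=["O"])

    def test_all_outside_corpus_predicts_outside(self, lexicons):
        (x, _, _, _) = _toy_corpus(lexicons)[0]
        model = train_crf([(x, ["O"] * len(x))], max_iterations=20)
        assert predict_labels(model, x) == ["O"] * len(x)

    def test_empty_sequence_predicts_empty(self, lexicons):
        (x, y, _, _) = _toy_corpus(lexicons)[0]
        model = train_crf([(x, y)], max_iterations=20)
        assert model.predict([]) == []

    def test_template_mismatch_raises(self, lexicons):
        (x, y, _, _) = _toy_corpus(lexicons)[0]
        model = train_crf([(x, y)], max_iterations=10)
        model.template_version = "other"
        with pytest.raises(CRFError):
            predict_labels(model, x)


class TestPersistence:
    def test_save_load_predicts_bit_identically(self, lexicons, tmp_path):
        seqs = _toy_corpus(lexicons)
        model = train_crf([(x, y) for x, y, _, _ in seqs], max_iterations=60)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = LinearChainCRF.load(path)
        for x, _, _, _ in seqs:
            assert loaded.predict(x) == model.predict(x)
        np.testing.assert_array_equal(loaded.w_state, model.w_state)
        np.testing.assert_array_equal(loaded.w_trans, model.w_trans)

    def test_two_loads_identical_transitions(self, lexicons, tmp_path):
        (x, y, _, _) = _toy_corpus(lexicons)[0]
        model = train_crf([(x, y)], max_iterations=20)
        path = tmp_path / "m.json"
        model.save(path)
        a = extract_transition_scores(LinearChainCRF.load(path))
        b = extract_transition_scores(LinearChainCRF.load(path))
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_untrained_model_refuses(self):
        with pytest.raises(CRFError):
            LinearChainCRF().predict([{"bias": 1.0}])
        with pytest.raises(CRFError):
            extract_transition_scores(LinearChainCRF())


def entity_prf(test_seqs, predict):
    tp = fp = fn = 0
    for p in test_seqs:
        gold = {(e.type.value, e.start, e.end)
                for e in labels_to_entities(p.tokens, p.labels, p.norm_text)}
        pred = {(e.type.value, e.start, e.end) for e in predict(p)}
        tp += len(gold & pred)
        fp += len(pred - gold)
        fn += len(gold - pred)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


class TestTrainedModel:
    def test_training_beats_dictionary_baseline_on_train_tokens(
            self, prepared_split, trained_model, lexicons):
        train, _ = prepared_split
        sample = train[:100]
        crf_ok = dict_ok = total = 0
        for p in sample:
            pred = predict_labels(trained_model, p.features)
            base = spans_to_bio(p.tokens, [
                (e.start, e.end, e.type.value)
                for e in dictionary_tag(p.tokens, lexicons, p.norm_text)])
            crf_ok += sum(a == b for a, b in zip(pred, p.labels))
            dict_ok += sum(a == b for a, b in zip(base, p.labels))
            total += len(p.labels)
        assert crf_ok / total >= dict_ok / total

    def test_heldout_entity_f_at_least_090(self, prepared_split, trained_model):
        _, test = prepared_split
        _, _, f = entity_prf(
            test, lambda p: labels_to_entities(
                p.tokens, predict_labels(trained_model, p.features), p.norm_text))
        # target 0.9 with the stated stochastic tolerance of +/-0.05
        assert f >= 0.85

    def test_predictions_are_bio_valid(self, prepared_split, trained_model):
        _, test = prepared_split
        for p in test[:50]:
            assert is_valid_bio(predict_labels(trained_model, p.features))

    def test_measurement_transitions_favor_entities_over_segment(self, trained_model):
        tm = extract_transition_scores(trained_model)
        meas_to = lambda dst: tm.score("I-MEASUREMENT", f"B-{dst}")
        assert max(meas_to("ANATOMICAL_ENTITY"), meas_to("IMAGING_OBSERVATION")) \
            > meas_to("SEGMENT")

    def test_transition_matrix_square_over_label_set(self, trained_model):
        tm = extract_transition_scores(trained_model)
        k = len(bio_label_set(include_rule_labels=True))
        assert tm.scores.shape == (k, k)
        assert tm.labels == trained_model.labels
        norm = tm.normalized()
        np.testing.assert_allclose(norm.sum(axis=1), 1.0)


class TestBaselineDominance:
    def test_dictionary_recall_one_on_lexicon_only_text(self, lexicons):
        """When generated text uses only verbatim lexicon forms, the
        dictionary baseline must recall every gold entity."""
        from radmeasure.corpus import prepare_sequences
        from radmeasure.synthetic import GeneratorConfig, generate_corpus

        corpus = generate_corpus(GeneratorConfig(seed=23, n_reports=20, variant_rate=0.0))
        prepared = prepare_sequences(corpus.standoff, lexicons)
        _, recall, _ = entity_prf(
            prepared, lambda p: dictionary_tag(p.tokens, lexicons, p.norm_text))
        assert recall == 1.0
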