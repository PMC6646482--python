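import copy

import pytest
from hypothesis import given, strategies as st

from radmeasure import build_frames
from radmeasure.evaluation import (
    align_frames,
    classify_match,
    combination_match_table,
    compare_pipelines,
    evaluate_matches,
    match_counts,
    metrics_from_counts,
    metrics_table,
    score_descriptor,
)
from radmeasure.types import ConfusionCounts, MatchCategory, MeasurementFrame


def _frame(fid="f0", doc="d", sent=0, value=4.0, unit="mm", span=(0, 4), **slots):
    return MeasurementFrame(
        frame_id=fid, doc_id=doc, sentence_id=sent, value=value, unit=unit,
        dimensions=[value], measurement_span=span, surface=f"{value:g} {unit}",
        **slots)


class TestMetricsFromCounts:
    def test_measurement_row_of_published_count_triple(self):
        row = metrics_from_counts(ConfusionCounts(784, 29, 0)).rounded()
        assert (row.precision, row.recall, row.f_score) == (96.43, 100.0, 98.18)

    def test_perfect_extraction(self):
        row = metrics_from_counts(ConfusionCounts(10, 0, 0))
        assert (row.precision, row.recall, row.f_score) == (100.0, 100.0, 100.0)

    def test_balanced_errors(self):
        row = metrics_from_counts(ConfusionCounts(1, 1, 1))
        assert (row.precision, row.recall, row.f_score) == (50.0, 50.0, 50.0)

    def test_undefined_denominators_marked_not_zeroed(self):
        row = metrics_from_counts(ConfusionCounts(0, 0, 5))
        assert row.precision is None and row.recall == 0.0 and row.f_score is None

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_f_between_precision_and_recall(self, tp, fp, fn):
        row = metrics_from_counts(ConfusionCounts(tp, fp, fn))
        if row.precision is not None and row.recall is not None and row.f_score is not None:
            assert min(row.precision, row.recall) - 1e-9 <= row.f_score
            assert row.f_score <= max(row.precision, row.recall) + 1e-9


class TestScoreDescriptor:
    def test_temporality_agreement(self):
        s = _frame(temporality="PRIOR")
        g = _frame(temporality="PRIOR")
        c = score_descriptor([s], [g], "temporality")
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_image_number_equality_and_mismatch(self):
        s = _frame(image_number=127)
        assert score_descriptor([s], [_frame(image_number=127)], "image_number").tp == 1
        c = score_descriptor([s], [_frame(image_number=124)], "image_number")
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_missing_system_entity_is_fn(self):
        c = score_descriptor([_frame()], [_frame(anatomical_entity=["left frontal"])],
                             "anatomical_entity")
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_text_match_ignores_case_and_spacing(self):
        s = _frame(anatomical_entity=["Left  Frontal"])
        c = score_descriptor([s], [_frame(anatomical_entity=["left frontal"])],
                             "anatomical_entity")
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_unaligned_frames_count_fp_fn(self):
        s = _frame(value=9.0)  # different value: never aligns
        g = _frame(value=4.0, anatomical_entity=["liver"])
        assert score_descriptor([s], [g], "measurement").fp == 1
        assert score_descriptor([s], [g], "anatomical_entity").fn == 1


class TestClassifyMatch:
    def test_identical_frames_full(self):
        g = _frame(anatomical_entity=["liver"], imaging_observation=["mass"],
                   image_number=4)
        r = classify_match(copy.deepcopy(g), g)
        assert r.category is MatchCategory.FULL
        assert r.missed_descriptors == frozenset()

    def test_measurement_only_system_vs_rich_gold_no_match(self):
        g = _frame(temporality="PRIOR", anatomical_entity=["liver"],
                   imaging_observation=["mass"], radlex_descriptor=["cystic"])
        s = _frame(temporality="CURRENT")
        assert classify_match(s, g).category is MatchCategory.NO_MATCH

    def test_one_missed_descriptor_partial(self):
        g = _frame(anatomical_entity=["liver"], radlex_descriptor=["cystic"])
        s = _frame(anatomical_entity=["liver"])
        r = classify_match(s, g)
        assert r.category is MatchCategory.PARTIAL
        assert r.missed_descriptors == frozenset({"radlex_descriptor"})

    def test_vacuous_descriptors_count_toward_full(self):
        assert classify_match(_frame(), _frame()).category is MatchCategory.FULL

    def test_discussion_example_nine_of_ten_partial(
            self, discussion_sentence, discussion_gold, lexicons):
        system = build_frames("FINDINGS: " + discussion_sentence, lexicons, doc_id="disc")
        counts = match_counts(evaluate_matches(system, discussion_gold))
        assert counts["PARTIAL"] == 9
        assert counts["FULL"] == 1
        assert counts["NO_MATCH"] == 0


class TestMatchPartition:
    def test_categories_partition_gold(self, synth_corpus, lexicons):
        reports = synth_corpus.reports[:15]
        doc_ids = {r.doc_id for r in reports}
        gold = [f for f in synth_corpus.gold_frames if f.doc_id in doc_ids]
        system = [f for r in reports for f in build_frames(r, lexicons)]
        results = evaluate_matches(system, gold)
        counts = match_counts(results)
        assert sum(counts.values()) == len(gold)


class TestCombinationTable:
    def _results(self, system, gold):
        return evaluate_matches(system, gold)

    def test_empty_combination_covers_all(self, discussion_sentence,
                                          discussion_gold, lexicons):
        system = build_frames("FINDINGS: " + discussion_sentence, lexicons, doc_id="disc")
        table = combination_match_table(self._results(system, discussion_gold), [[]])
        assert table.loc[0, "count"] == 10
        assert table.loc[0, "percent"] == 100.0

    def test_constructed_ae_always_matched(self):
        gold = [_frame(fid=f"g{i}", span=(i * 10, i * 10 + 4),
                       anatomical_entity=["liver"]) for i in range(5)]
        system = [copy.deepcopy(g) for g in gold]
        table = combination_match_table(self._results(system, gold),
                                        [["anatomical_entity"]])
        assert table.loc[0, "count"] == 5

    def test_antitone_in_combination_inclusion(self, discussion_sentence,
                                               discussion_gold, lexicons):
        system = build_frames("FINDINGS: " + discussion_sentence, lexicons, doc_id="disc")
        chain = [[], ["anatomical_entity"],
                 ["anatomical_entity", "imaging_observation"],
                 ["anatomical_entity", "imaging_observation", "image_number"],
                 ["anatomical_entity", "imaging_observation", "image_number",
                  "radlex_descriptor"]]
        table = combination_match_table(self._results(system, discussion_gold), chain)
        counts = list(table["count"])
        assert counts == sorted(counts, reverse=True)


class TestComparePipelines:
    def test_identical_systems_identical_rows(self, discussion_sentence,
                                              discussion_gold, lexicons):
        system = build_frames("FINDINGS: " + discussion_sentence, lexicons, doc_id="disc")
        table = compare_pipelines(system, system, discussion_gold)
        for metric in ("precision", "recall", "f_score"):
            assert (table[f"baseline_{metric}"].fillna(-1)
                    == table[f"proposed_{metric}"].fillna(-1)).all()

    def test_baseline_without_radlex_has_zero_recall_row(self):
        gold = [_frame(radlex_descriptor=["cystic"])]
        baseline = [_frame()]
        proposed = [_frame(radlex_descriptor=["cystic"])]
        table = compare_pipelines(baseline, proposed, gold).set_index("information_type")
        assert table.loc["radlex_descriptor", "baseline_recall"] == 0.0
        assert table.loc["radlex_descriptor", "proposed_recall"] == 100.0

    def test_crf_entity_recall_at_least_baseline(self, synth_corpus, lexicons,
                                                 trained_model):
        """With out-of-lexicon surface variants injected, the CRF pipeline's
        entity recall should not fall below the dictionary baseline's."""
        reports = synth_corpus.reports[-12:]
        doc_ids = {r.doc_id for r in reports}
        gold = [f for f in synth_corpus.gold_frames if f.doc_id in doc_ids]
        base = [f for r in reports for f in build_frames(r, lexicons)]
        crf = [f for r in reports for f in build_frames(r, lexicons, model=trained_model)]
        table = compare_pipelines(base, crf, gold).set_index("information_type")
        for row in ("anatomical_entity", "imaging_observation", "radlex_descriptor"):
            assert table.loc[row, "proposed_recall"] >= table.loc[row, "baseline_recall"]


class TestAlignment:
    def test_best_scoring_pairing_wins(self):
        gold = [_frame(fid="g", anatomical_entity=["liver"])]
        bad = _frame(fid="s-bad")
        good = _frame(fid="s-good", anatomical_entity=["liver"])
        pairs, unmatched_s, _ = align_frames([bad, good], gold)
        assert pairs == [(good, gold[0])]
        assert unmatched_s == [bad]

    def test_value_unit_must_agree(self):
        assert align_frames([_frame(unit="cm")], [_frame(unit="mm")])[0] == []

    def test_metrics_table_has_all_information_types(self):
        g = _frame(anatomical_entity=["liver"])
        table = metrics_table([copy.deepcopy(g)], [g])
        assert list(table["information_type"]) == [
            "measurement", "temporality", "anatomical_entity",
            "imaging_observation", "radlex_descriptor", "image_number",
            "series_number", "segment"]
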