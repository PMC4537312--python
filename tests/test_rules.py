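"""Behaviour of the removal cascade and retain overrides."""

import pytest

from ademiner import (
    RuleConfig,
    ValidationError,
    annotate_corpus,
    annotate_document,
    apply_removal_stages,
    apply_retain_rules,
    find_candidate_mentions,
    score_annotations,
)
from ademiner.gazetteer import CANDIDATE, REMOVED, RETAINED
from ademiner.synth import GeneratorSpec, generate_corpus
from conftest import make_doc


def annotate_one(text, lexicons, gazetteers, config=RuleConfig()):
    mentions = annotate_document(make_doc(text), lexicons, gazetteers, config)
    assert len(mentions) == 1, f"expected one mention in {text!r}"
    return mentions[0]


class TestRemovalStages:
    @pytest.mark.parametrize(
        "text, stage_id",
        [
            ("Did not have dystonia.", "S1.negation_before"),
            ("No evidence of dystonia on examination.", "S1.negation_before"),
            ("Dystonia was ruled out by neurology.", "S2.negation_after"),
            ("Dystonia Society have always been a useful resource.", "S3.organisation"),
            ("She attended a dystonia workshop.", "S3.organisation"),
            ("Any signs of dystonia?", "S4.symbol_punctuation"),
            ("Noted dystonia / tremor on the chart.", "S4.symbol_punctuation"),
            ("Mother had developed dystonia many years ago.", "S5.other_person"),
            ("Check for any dystonic reaction.", "S6.monitor"),
            ("Possibility of dystonia with ZZZZZ.", "S7.negative_effects"),
            ("We warned about dystonia before treatment.", "S7.negative_effects"),
            ("Movement disorders like dystonia are common.", "S8.single_word_context"),
            ("For any dystonia consider procyclidine.", "S8.single_word_context"),
            ("These thoughts are ego dystonic in nature.", "S9.diagnosis_homonym"),
            ("Patient was given a leaflet about dystonia.", "S10.drug_effects"),
            ("If Dystonia develops give procyclidine dose.", "S11.hypothetical"),
        ],
    )
    def test_each_stage_fires_on_its_context(self, text, stage_id, dystonia_lexicons, gazetteers):
        m = annotate_one(text, dystonia_lexicons, gazetteers)
        assert m.status == REMOVED
        assert stage_id in m.fired_rules

    def test_no_cue_stays_candidate(self, dystonia_lexicons, gazetteers):
        m = annotate_one("Patient developed dystonia overnight.", dystonia_lexicons, gazetteers)
        assert m.status == CANDIDATE
        assert m.fired_rules == []

    def test_all_stage_decisions_reported_in_order(self, dystonia_lexicons, gazetteers):
        doc = make_doc("Did not have dystonia.")
        (m,) = find_candidate_mentions(doc, dystonia_lexicons)
        decisions = apply_removal_stages(m, doc, gazetteers)
        assert len(decisions) == 11
        assert [d.stage_id.split(".")[0] for d in decisions] == [f"S{k}" for k in range(1, 12)]
        fired = [d for d in decisions if d.action == "remove"]
        assert fired and all(d.trigger_term for d in fired)

    def test_cue_outside_window_does_not_fire(self, dystonia_lexicons, gazetteers):
        # negation cue 6 word-tokens upstream of the mention: outside window 5
        text = "Not seen since admission early last autumn morning dystonia persisted."
        m = annotate_one(text, dystonia_lexicons, gazetteers)
        assert "S1.negation_before" not in m.fired_rules
        wide = RuleConfig(window_before=10, window_after=10)
        m2 = annotate_one(text, dystonia_lexicons, gazetteers, wide)
        assert "S1.negation_before" in m2.fired_rules

    def test_cue_in_another_sentence_never_fires(self, dystonia_lexicons, gazetteers):
        m = annotate_one("His mother is unwell. Dystonia worse today.", dystonia_lexicons, gazetteers)
        assert m.status == CANDIDATE

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValidationError, match="unknown removal stage"):
            RuleConfig(enabled_removal_stages=(1, 13))

    def test_window_must_be_positive(self):
        with pytest.raises(ValidationError, match="window"):
            RuleConfig(window_before=0)


class TestRetainRules:
    def test_possessive_overrides_removal(self, dystonia_lexicons, gazetteers):
        doc = make_doc("Her dystonia had become worse.")
        (m,) = find_candidate_mentions(doc, dystonia_lexicons)
        m.status = REMOVED  # as if some removal stage had fired
        decisions = apply_retain_rules(m, doc, gazetteers)
        assert any(d.action == "retain" for d in decisions)
        assert m.status == RETAINED

    def test_definite_article_override_end_to_end(self, dystonia_lexicons, gazetteers):
        m = annotate_one(
            "The patient does not think the dystonia was painful.", dystonia_lexicons, gazetteers
        )
        assert m.status == RETAINED
        assert "S1.negation_before" in m.fired_rules
        assert "S12.retain_definite_possessive" in m.fired_rules

    def test_diagnostic_phrase_retains(self, dystonia_lexicons, gazetteers):
        m = annotate_one("She was diagnosed with dystonia in March.", dystonia_lexicons, gazetteers)
        assert m.is_positive

    def test_patient_plus_indication_retains(self, dystonia_lexicons, gazetteers):
        doc = make_doc("Patient had a severe dystonia reaction yesterday.")
        (m,) = find_candidate_mentions(doc, dystonia_lexicons)
        decisions = apply_retain_rules(m, doc, gazetteers)
        assert any(d.stage_id == "S12.retain_patient_indication" for d in decisions)

    def test_no_cue_no_decision(self, dystonia_lexicons, gazetteers):
        doc = make_doc("Marked dystonia on examination.")
        (m,) = find_candidate_mentions(doc, dystonia_lexicons)
        assert apply_retain_rules(m, doc, gazetteers) == []
        assert m.status == CANDIDATE

    def test_retain_disabled_leaves_removal(self, dystonia_lexicons, gazetteers):
        cfg = RuleConfig(retain_enabled=False)
        m = annotate_one(
            "The patient does not think the dystonia was painful.",
            dystonia_lexicons,
            gazetteers,
            cfg,
        )
        assert m.status == REMOVED


@pytest.fixture(scope="module")
def corpus():
    return generate_corpus(GeneratorSpec(n_patients=60, ade_ids=("dystonia", "akathisia"), seed=3))


class TestPipelineProperties:

    def test_monotone_removal(self, corpus, epse_lexicons, gazetteers):
        counts = []
        for k in range(0, 12):
            cfg = RuleConfig(enabled_removal_stages=tuple(range(1, k + 1)), retain_enabled=False)
            mentions = annotate_corpus(corpus.documents, epse_lexicons, gazetteers, cfg)
            counts.append(sum(m.is_positive for m in mentions))
        assert counts == sorted(counts, reverse=True)

    def test_retain_never_decreases_positives(self, corpus, epse_lexicons, gazetteers):
        without = annotate_corpus(
            corpus.documents, epse_lexicons, gazetteers, RuleConfig(retain_enabled=False)
        )
        with_retain = annotate_corpus(corpus.documents, epse_lexicons, gazetteers, RuleConfig())
        assert sum(m.is_positive for m in with_retain) >= sum(m.is_positive for m in without)

    def test_pipeline_recall_not_above_keyword_recall(self, corpus, epse_lexicons, gazetteers):
        keyword = annotate_corpus(
            corpus.documents, epse_lexicons, gazetteers, RuleConfig.keyword_only()
        )
        pipeline = annotate_corpus(corpus.documents, epse_lexicons, gazetteers, RuleConfig())
        r_kw = score_annotations(keyword, corpus.gold_labels).recall
        r_pipe = score_annotations(pipeline, corpus.gold_labels).recall
        assert r_pipe <= r_kw

    def test_rules_never_alter_spans(self, corpus, epse_lexicons, gazetteers):
        keyword = annotate_corpus(
            corpus.documents, epse_lexicons, gazetteers, RuleConfig.keyword_only()
        )
        pipeline = annotate_corpus(corpus.documents, epse_lexicons, gazetteers, RuleConfig())
        assert [(m.doc_id, m.start, m.end) for m in keyword] == [
            (m.doc_id, m.start, m.end) for m in pipeline
        ]

    def test_deterministic_for_fixed_inputs(self, corpus, epse_lexicons, gazetteers):
        a = annotate_corpus(corpus.documents, epse_lexicons, gazetteers, RuleConfig())
        b = annotate_corpus(corpus.documents, epse_lexicons, gazetteers, RuleConfig())
        assert [(m.doc_id, m.start, m.status, tuple(m.fired_rules)) for m in a] == [
            (m.doc_id, m.start, m.status, tuple(m.fired_rules)) for m in b
        ]
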