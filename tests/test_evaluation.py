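"""Scoring, cumulative ablation and inter-annotator agreement."""

import random

import pytest
from sklearn.metrics import cohen_kappa_score

from ademiner import (
    EvalResult,
    GoldLabel,
    Mention,
    RuleConfig,
    ValidationError,
    annotate_corpus,
    cumulative_stage_report,
    inter_annotator_agreement,
    score_annotations,
)
from ademiner.synth import GeneratorSpec, generate_corpus


def mention(doc_id, start, end, status="candidate", ade_id="dystonia"):
    return Mention(
        doc_id=doc_id, ade_id=ade_id, start=start, end=end,
        matched_term="x" * (end - start), sentence_index=0, status=status,
    )


def brute_force_confusion(predicted, gold):
    """Independent O(n^2) recount of the mention-level confusion."""
    pred_pos = [m for m in predicted if m.status in ("candidate", "retained")]
    gold_pos = [g for g in gold if g.label == "positive"]

    def overlaps(m, g):
        return (
            m.doc_id == g.doc_id and m.ade_id == g.ade_id
            and m.start < g.end and g.start < m.end
        )

    tp = sum(any(overlaps(m, g) for g in gold_pos) for m in pred_pos)
    fp = len(pred_pos) - tp
    fn = sum(not any(overlaps(m, g) for m in pred_pos) for g in gold_pos)
    return tp, fp, fn


class TestScoreAnnotations:
    def test_precision_recall_by_definition(self):
        r = EvalResult(tp=3, fp=1, fn=2)
        assert r.precision == 0.75
        assert r.recall == 0.6

    def test_perfect_when_predictions_equal_gold(self):
        gold = [GoldLabel("d1", 0, 8, "dystonia", "positive")]
        pred = [mention("d1", 0, 8)]
        r = score_annotations(pred, gold)
        assert (r.precision, r.recall) == (1.0, 1.0)

    def test_removed_mentions_are_not_positives(self):
        gold = [GoldLabel("d1", 0, 8, "dystonia", "positive")]
        r = score_annotations([mention("d1", 0, 8, status="removed")], gold)
        assert (r.tp, r.fp, r.fn) == (0, 0, 1)

    def test_exact_span_policy_rejects_partial_overlap(self):
        gold = [GoldLabel("d1", 0, 8, "dystonia", "positive")]
        pred = [mention("d1", 0, 6)]
        assert score_annotations(pred, gold, "exact-span").tp == 0
        assert score_annotations(pred, gold, "overlap").tp == 1

    def test_undefined_precision_is_none_with_warning(self):
        gold = [GoldLabel("d1", 0, 8, "dystonia", "positive")]
        r = score_annotations([], gold)
        with pytest.warns(UserWarning, match="undefined"):
            assert r.precision is None
        assert r.recall == 0.0

    def test_gold_span_outside_document_rejected(self):
        from conftest import make_doc

        docs = {"d1": make_doc("short", doc_id="d1")}
        gold = [GoldLabel("d1", 0, 99, "dystonia", "positive")]
        with pytest.raises(ValidationError, match="not found"):
            score_annotations([], gold, documents=docs)

    def test_matches_brute_force_oracle_on_generated_corpus(
        self, epse_lexicons, gazetteers
    ):
        corpus = generate_corpus(
            GeneratorSpec(n_patients=70, ade_ids=("dystonia", "akathisia"), seed=21)
        )
        # degrade the pipeline so the confusion is non-trivial
        cfg = RuleConfig(enabled_removal_stages=(1, 5, 7), retain_enabled=False)
        predicted = annotate_corpus(corpus.documents, epse_lexicons, gazetteers, cfg)
        r = score_annotations(predicted, corpus.gold_labels)
        assert (r.tp, r.fp, r.fn) == brute_force_confusion(predicted, corpus.gold_labels)
        assert r.fp > 0 and r.fn > 0  # genuinely mixed confusion

    def test_document_order_irrelevant(self, epse_lexicons, gazetteers):
        corpus = generate_corpus(GeneratorSpec(n_patients=30, seed=5))
        predicted = annotate_corpus(corpus.documents, epse_lexicons, gazetteers)
        r1 = score_annotations(predicted, corpus.gold_labels)
        r2 = score_annotations(list(reversed(predicted)), list(reversed(corpus.gold_labels)))
        assert (r1.tp, r1.fp, r1.fn) == (r2.tp, r2.fp, r2.fn)


class TestCumulativeStageReport:
    def test_rows_and_monotone_positive_count(self, dystonia_lexicons, gazetteers):
        corpus = generate_corpus(GeneratorSpec(n_patients=60, seed=13))
        rows = cumulative_stage_report(
            corpus.documents, corpus.gold_labels, dystonia_lexicons, gazetteers
        )
        assert [r.stage_label for r in rows] == (
            ["keyword-only"] + [f"through S{k}" for k in range(1, 12)] + ["with retain"]
        )
        removal_counts = [r.n_positive for r in rows[:-1]]
        assert removal_counts == sorted(removal_counts, reverse=True)
        assert rows[-1].n_positive >= rows[-2].n_positive

    def test_precision_jumps_exactly_at_the_only_negative_family(
        self, dystonia_lexicons, gazetteers
    ):
        mix = {f: 0.0 for f in ("retain_positive", "negation", "monitoring", "warning",
                                "organisation", "hypothetical", "diagnosis_homonym",
                                "symbol_adjacent", "drug_listing")}
        mix.update({"plain_positive": 0.7, "other_person": 0.3})
        corpus = generate_corpus(GeneratorSpec(n_patients=80, context_mix=mix, seed=17))
        rows = cumulative_stage_report(
            corpus.documents, corpus.gold_labels, dystonia_lexicons, gazetteers
        )
        prec = [r.result.precision for r in rows]
        # all negatives are other-person contexts: precision changes only at
        # the row that first enables S5 (row k = "through S_k")
        assert prec[4] < prec[5] == 1.0
        assert prec[0] == prec[4]
        assert all(p == 1.0 for p in prec[5:])

    def test_keyword_row_perfect_on_cue_free_corpus(self, dystonia_lexicons, gazetteers):
        mix = {f: 0.0 for f in ("retain_positive", "negation", "monitoring", "warning",
                                "organisation", "hypothetical", "diagnosis_homonym",
                                "symbol_adjacent", "drug_listing", "other_person")}
        mix["plain_positive"] = 1.0
        corpus = generate_corpus(GeneratorSpec(n_patients=30, context_mix=mix, seed=19))
        rows = cumulative_stage_report(
            corpus.documents, corpus.gold_labels, dystonia_lexicons, gazetteers
        )
        assert rows[0].result.precision == 1.0
        assert rows[0].result.recall == 1.0


class TestAgreement:
    def test_identical_vectors(self):
        labels = {i: ("positive" if i % 3 else "negative") for i in range(30)}
        res = inter_annotator_agreement(labels, dict(labels))
        assert res.percent_agreement == 100.0
        assert res.kappa == 1.0

    def test_chance_level_agreement_gives_zero_kappa(self):
        # A all positive; B half/half: p_o = 0.5 = p_e, kappa = 0
        a = {i: "positive" for i in range(40)}
        b = {i: ("positive" if i < 20 else "negative") for i in range(40)}
        res = inter_annotator_agreement(a, b)
        assert res.p_o == pytest.approx(res.p_e) == 0.5
        assert res.kappa == pytest.approx(0.0)

    def test_planted_contingency_table_matches_brute_force(self):
        # 2x2 agreement table: both-pos 20, A-pos/B-neg 5, A-neg/B-pos 10, both-neg 15
        cells = {("positive", "positive"): 20, ("positive", "negative"): 5,
                 ("negative", "positive"): 10, ("negative", "negative"): 15}
        a, b, i = {}, {}, 0
        for (la, lb), n in cells.items():
            for _ in range(n):
                a[i], b[i] = la, lb
                i += 1
        n = i
        p_o = (20 + 15) / n
        p_a_pos = (20 + 5) / n
        p_b_pos = (20 + 10) / n
        p_e = p_a_pos * p_b_pos + (1 - p_a_pos) * (1 - p_b_pos)
        expected_kappa = (p_o - p_e) / (1 - p_e)
        res = inter_annotator_agreement(a, b)
        assert res.kappa == pytest.approx(expected_kappa, abs=1e-12)

    def test_agrees_with_sklearn_on_random_vectors(self):
        rng = random.Random(4)
        keys = list(range(200))
        a = {k: rng.choice(["positive", "negative"]) for k in keys}
        b = {k: (a[k] if rng.random() < 0.8 else rng.choice(["positive", "negative"])) for k in keys}
        res = inter_annotator_agreement(a, b)
        sk = cohen_kappa_score([a[k] for k in keys], [b[k] for k in keys])
        assert res.kappa == pytest.approx(sk, abs=1e-12)

    def test_symmetry(self):
        rng = random.Random(9)
        a = {k: rng.choice(["positive", "negative"]) for k in range(50)}
        b = {k: rng.choice(["positive", "negative"]) for k in range(50)}
        r1, r2 = inter_annotator_agreement(a, b), inter_annotator_agreement(b, a)
        assert r1.kappa == pytest.approx(r2.kappa, abs=1e-15)
        assert r1.percent_agreement == r2.percent_agreement

    def test_mismatched_item_sets_rejected(self):
        with pytest.raises(ValidationError, match="different item sets"):
            inter_annotator_agreement({1: "positive"}, {2: "positive"})
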