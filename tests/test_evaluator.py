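"""Cascade scoring: fragment matching, corpus evaluation, metric
arithmetic and report formatting."""

import random

import pytest

from belscore import (
    LEVELS,
    MetricCounts,
    evaluate_corpus,
    format_percent,
    format_report,
    match_fragments,
    parse_term,
    precision_recall_f,
    terms_equivalent,
)
from belscore.fixtures import PerturbationSpec, generate_corpus, perturb

from conftest import FIG1_GOLD, brute_force_matching


def _terms(*texts):
    return [parse_term(t) for t in texts]


def _as_lines(corpus):
    from belscore import serialize_statement
    return {rec.evidence_id: [serialize_statement(s) for s in rec.statements]
            for rec in corpus}


class TestMatchFragments:
    def test_identical_sets_all_true_positive(self):
        g = _terms("p(HGNC:A)", "p(HGNC:B)")
        c = match_fragments(g, list(g))
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_missing_prediction_is_false_negative(self):
        c = match_fragments(_terms("p(HGNC:IL1B)", "p(HGNC:ATF2)"),
                            _terms("p(HGNC:IL1B)"))
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_extra_prediction_is_false_positive(self):
        c = match_fragments(_terms("p(HGNC:A)"), _terms("p(HGNC:B)", "p(HGNC:A)"))
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_matches_exhaustive_enumeration_on_small_instances(self, gene_map):
        """Maximum-matching credit equals the brute-force optimum on
        random instances with overlapping equivalence classes."""
        rng = random.Random(1234)
        pool = _terms(
            "p(HGNC:GENE1)", "g(EGID:10001)", "p(MGI:Gene1mus)",
            "p(HGNC:GENE2)", "r(EGID:10002)", "p(MGI:Gene2mus)",
            "p(HGNC:OTHER)", 'a(CHEBI:"calcium(2+)")', "bp(GOBP:apoptosis)",
            "complex(p(HGNC:GENE1), p(HGNC:OTHER))")
        predicate = lambda a, b: terms_equivalent(a, b, gene_map)
        for _ in range(250):
            gold = rng.sample(pool, rng.randint(0, 6))
            pred = [rng.choice(pool) for _ in range(rng.randint(0, 6))]
            got = match_fragments(gold, pred, gene_map)
            want_tp = brute_force_matching(gold, pred, predicate)
            assert got.tp == want_tp
            assert got.fn == len(gold) - want_tp
            assert got.fp == len(pred) - want_tp


class TestPrecisionRecallF:
    def test_published_retrieval_precision_arithmetic(self):
        s = precision_recall_f(MetricCounts(tp=117, fp=265, fn=0))
        assert format_percent(s.precision)[:4] == "30.6"

    def test_empty_counts_give_zero(self):
        s = precision_recall_f(MetricCounts())
        assert (s.precision, s.recall, s.f_score) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("x", [0.1, 0.5, 0.97])
    def test_f_equals_p_and_r_when_equal(self, x):
        n = 100
        tp = int(x * n)
        s = precision_recall_f(MetricCounts(tp=tp, fp=n - tp, fn=n - tp))
        assert s.precision == s.recall == pytest.approx(s.f_score)

    def test_f_between_p_and_r(self):
        s = precision_recall_f(MetricCounts(tp=30, fp=10, fn=50))
        assert min(s.precision, s.recall) <= s.f_score <= max(s.precision, s.recall)


class TestEvaluateCorpus:
    def test_relation_flip_against_gold_cascades_as_documented(self):
        gold = {"e1": [FIG1_GOLD]}
        pred = {"e1": ["p(HGNC:IL1B) decreases p(HGNC:ATF2)"]}
        r = evaluate_corpus(gold, pred)
        expect = {
            "term": (2, 0, 0), "function": (0, 0, 1),
            "function_secondary": (0, 0, 1), "relation": (0, 1, 1),
            "relation_secondary": (1, 0, 0), "statement": (0, 1, 1),
        }
        for lv, (tp, fp, fn) in expect.items():
            c = r.counts[lv]
            assert (c.tp, c.fp, c.fn) == (tp, fp, fn), lv

    def test_empty_prediction_corpus(self):
        gold = {"e1": [FIG1_GOLD]}
        r = evaluate_corpus(gold, {"e1": []})
        for lv in LEVELS:
            assert r.scores[lv].recall == 0.0
            assert r.counts[lv].fp == 0

    def test_identity_corpus_is_perfect(self):
        corpus = generate_corpus(25, seed=2)
        lines = _as_lines(corpus)
        r = evaluate_corpus(corpus, lines)
        for lv in LEVELS:
            s = r.scores[lv]
            assert s.precision == s.recall == s.f_score == 1.0
            assert r.no_correct_prediction_sentences[lv] == 0

    def test_invalid_predictions_ignored_and_counted(self):
        gold = {"e1": [FIG1_GOLD]}
        pred = {"e1": ["p(HGNC:IL1B increases", "bp(HGNC:TNF) increases p(HGNC:A)"]}
        r = evaluate_corpus(gold, pred)
        assert r.ignored_invalid == 2
        for lv in LEVELS:
            assert r.counts[lv].fp == 0

    def test_orphan_prediction_evidence_warns_and_counts_fp(self):
        gold = {"e1": [FIG1_GOLD]}
        pred = {"e1": [FIG1_GOLD], "e999": ["p(HGNC:A) increases p(HGNC:B)"]}
        with pytest.warns(UserWarning, match="absent from gold"):
            r = evaluate_corpus(gold, pred)
        assert r.counts["statement"].fp == 1

    def test_swapping_corpora_exchanges_precision_and_recall(self):
        corpus = generate_corpus(40, seed=9)
        pred, _ = perturb(corpus, PerturbationSpec("entity_swap", 0.5, seed=4))
        gold_lines = _as_lines(corpus)
        fwd = evaluate_corpus(gold_lines, pred)
        rev = evaluate_corpus(pred, gold_lines)
        for lv in LEVELS:
            assert fwd.scores[lv].precision == pytest.approx(rev.scores[lv].recall)
            assert fwd.scores[lv].recall == pytest.approx(rev.scores[lv].precision)

    def test_no_correct_prediction_sentences_counted(self):
        gold = {"e1": [FIG1_GOLD], "e2": ["p(HGNC:A) increases p(HGNC:B)"]}
        pred = {"e1": ["p(HGNC:OTHER) increases p(HGNC:NOPE)"], "e2": []}
        r = evaluate_corpus(gold, pred)
        assert r.no_correct_prediction_sentences["statement"] == 2
        assert r.no_correct_prediction_sentences["term"] == 2

    def test_conservation_and_monotonicity_on_fixture_run(self):
        corpus = generate_corpus(80, seed=17)
        specs = [PerturbationSpec("relation_flip", 0.2, seed=3),
                 PerturbationSpec("function_drop", 0.2, seed=3),
                 PerturbationSpec("entity_swap", 0.2, seed=3)]
        pred, _ = perturb(corpus, specs)
        r = evaluate_corpus(corpus, pred)
        # gold fragment totals = TP of the gold-vs-gold identity run
        ident = evaluate_corpus(corpus, _as_lines(corpus))
        pred_ident = evaluate_corpus(pred, pred)
        for lv in LEVELS:
            c = r.counts[lv]
            assert c.tp + c.fn == ident.counts[lv].tp          # TP+FN = |gold|
            assert c.tp + c.fp == pred_ident.counts[lv].tp     # TP+FP = |valid pred|
        # cascade monotonicity
        assert r.counts["statement"].tp <= r.counts["relation"].tp
        assert r.counts["relation"].tp <= r.counts["relation_secondary"].tp
        assert r.counts["function"].tp <= r.counts["function_secondary"].tp


class TestFormatting:
    def test_round_half_up_to_two_decimals(self):
        assert format_percent(0.49596) == "49.60"
        assert format_percent(0.63235) == "63.24"  # ties go up
        assert format_percent(0.0) == "0.00"
        assert format_percent(1.0) == "100.00"

    def test_report_layout_has_all_levels(self):
        corpus = generate_corpus(5, seed=1)
        text = format_report(evaluate_corpus(corpus, _as_lines(corpus)))
        for title in ("Terms", "Function-Secondary", "Relation-Secondary", "Statement"):
            assert title in text
        assert "100.00" in text
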