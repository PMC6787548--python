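"""Ranked evidence-retrieval metrics: support precision, AP/MAP,
inter-annotator kappa and the weighted ranking score."""

import pytest

from belscore import (
    ClassifierProbs,
    RankedEvidence,
    RankWeights,
    SentenceJudgment,
    average_precision,
    cohen_kappa,
    combine_ranking_score,
    evaluate_retrieval,
    load_ranked_evidence,
    mean_average_precision,
    micro_precision,
)


def _evidence(sid, labels):
    return RankedEvidence(sid, tuple(
        SentenceJudgment(pmid=f"pm{i}", sentence=f"s{i}", label=lab)
        for i, lab in enumerate(labels)))


def _labeled_pool(n_fully, n_partially, n_not, per_statement=5):
    """Evidence lists realizing exact pooled label counts."""
    labels = (["fully"] * n_fully + ["partially"] * n_partially
              + ["not_supportive"] * n_not)
    return [_evidence(f"st{i}", labels[i:i + per_statement])
            for i in range(0, len(labels), per_statement)]


class TestMicroPrecision:
    def test_pooled_precision_from_known_counts(self):
        evidences = _labeled_pool(121, 71, 190)
        counts, prec = micro_precision(evidences, "full")
        assert (counts.tp, counts.fp) == (121, 261)
        assert round(prec * 100, 1) == 31.7

    def test_partial_criterion_is_superset_of_full(self):
        evidences = _labeled_pool(20, 30, 50)
        full, p_full = micro_precision(evidences, "full")
        partial, p_partial = micro_precision(evidences, "partial")
        assert partial.tp >= full.tp
        assert p_partial >= p_full

    def test_all_fully_supportive_is_perfect_under_both(self):
        evidences = [_evidence("a", ["fully"] * 4)]
        assert micro_precision(evidences, "full")[1] == 1.0
        assert micro_precision(evidences, "partial")[1] == 1.0

    def test_empty_submission_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty submission"):
            _, prec = micro_precision([], "full")
        assert prec == 0.0

    def test_mean_sentences_per_statement(self):
        # 88 statements with 4 sentences + 10 with 3 = 382 over 98
        evidences = [_evidence(f"s{i}", ["fully"] * (4 if i < 88 else 3))
                     for i in range(98)]
        report = evaluate_retrieval(evidences)
        assert (report.n_sentences, report.n_statements) == (382, 98)
        assert round(report.n_sentences / report.n_statements, 1) == 3.9


class TestAveragePrecision:
    @pytest.mark.parametrize("flags,expected", [
        ([True, True, True], 1.0),
        ([False, True], 0.5),
        ([True, False, True], (1 + 2 / 3) / 2),
        ([], 0.0),
        ([False, False], 0.0),
    ])
    def test_direct_formula(self, flags, expected):
        assert average_precision(flags) == pytest.approx(expected)

    def test_promoting_a_relevant_sentence_never_hurts(self):
        """Swapping adjacent (irrelevant, relevant) so the relevant one
        moves up never decreases AP."""
        import itertools
        for flags in itertools.product([True, False], repeat=5):
            flags = list(flags)
            for i in range(4):
                if not flags[i] and flags[i + 1]:
                    promoted = flags.copy()
                    promoted[i], promoted[i + 1] = promoted[i + 1], promoted[i]
                    assert average_precision(promoted) >= average_precision(flags)


class TestMeanAveragePrecision:
    def test_mean_of_per_statement_ap(self):
        evidences = [_evidence("a", ["fully", "fully"]),
                     _evidence("b", ["not_supportive", "fully"])]
        assert mean_average_precision(evidences, "full") == pytest.approx(0.75)

    def test_statements_without_hits_count_zero(self):
        evidences = [_evidence("a", ["fully"]), _evidence("b", []),
                     _evidence("c", ["not_supportive"])]
        assert mean_average_precision(evidences, "full") == pytest.approx(1 / 3)

    def test_single_statement_map_equals_its_ap(self):
        ev = _evidence("a", ["not_supportive", "fully", "fully"])
        want = average_precision([False, True, True])
        assert mean_average_precision([ev], "full") == pytest.approx(want)

    def test_partially_supportive_counts_under_partial_criterion(self):
        ev = _evidence("a", ["partially"])
        assert mean_average_precision([ev], "full") == 0.0
        assert mean_average_precision([ev], "partial") == 1.0


def _kappa_oracle(table):
    """Brute-force kappa from a 2x2 confusion table [[aa, ab], [ba, bb]]."""
    n = sum(sum(row) for row in table)
    p_o = (table[0][0] + table[1][1]) / n
    a_first = (table[0][0] + table[0][1]) / n
    b_first = (table[0][0] + table[1][0]) / n
    p_e = a_first * b_first + (1 - a_first) * (1 - b_first)
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_identical_labelings(self):
        k, agreement = cohen_kappa(["y", "n", "y"], ["y", "n", "y"])
        assert k == 1.0 and agreement == 1.0

    def test_chance_level_agreement_is_zero(self):
        k, agreement = cohen_kappa(list("yynn"), list("ynyn"))
        assert k == pytest.approx(0.0)
        assert agreement == 0.5

    def test_against_confusion_table_oracle(self):
        table = [[50, 10], [10, 30]]
        labels_a = ["y"] * 60 + ["n"] * 40
        labels_b = ["y"] * 50 + ["n"] * 10 + ["y"] * 10 + ["n"] * 30
        k, agreement = cohen_kappa(labels_a, labels_b)
        assert k == pytest.approx(_kappa_oracle(table))
        assert k <= agreement

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            cohen_kappa(["y"], ["y", "n"])

    def test_kappa_never_exceeds_raw_agreement(self):
        import random
        rng = random.Random(7)
        for _ in range(30):
            a = [rng.choice("yn") for _ in range(40)]
            b = [rng.choice("yn") for _ in range(40)]
            k, agreement = cohen_kappa(a, b)
            assert k <= agreement + 1e-12


class TestRankingScore:
    def test_default_weights_combine_to_unity(self):
        assert combine_ranking_score(ClassifierProbs(1, 1, 1)) == pytest.approx(1.0)
        assert combine_ranking_score(ClassifierProbs(0, 0, 0)) == 0.0
        assert combine_ranking_score(ClassifierProbs(0.5, 0.5, 0.5)) == pytest.approx(0.5)

    def test_default_weights_are_documented_values(self):
        w = RankWeights()
        assert (w.w_ee, w.w_fe, w.w_r) == (0.4, 0.5, 0.1)

    def test_monotone_in_each_probability(self):
        base = combine_ranking_score(ClassifierProbs(0.2, 0.3, 0.4))
        assert combine_ranking_score(ClassifierProbs(0.9, 0.3, 0.4)) > base
        assert combine_ranking_score(ClassifierProbs(0.2, 0.9, 0.4)) > base
        assert combine_ranking_score(ClassifierProbs(0.2, 0.3, 0.9)) > base


class TestSubmissionFiles:
    def _write(self, tmp_path):
        sub = tmp_path / "sub.tsv"
        sub.write_text(
            "st1\t1\t111\tFirst evidence sentence.\n"
            "st1\t2\t222\tSecond evidence sentence.\n"
            "st2\t1\t333\tAnother one.\n")
        labels = tmp_path / "labels.tsv"
        labels.write_text(
            "st1\t1\tfully\nst1\t2\tnot_supportive\nst2\t1\tpartially\n")
        return sub, labels

    def test_join_and_order(self, tmp_path):
        sub, labels = self._write(tmp_path)
        evidences = {ev.statement_id: ev for ev in load_ranked_evidence(sub, labels)}
        assert [s.label for s in evidences["st1"].sentences] == ["fully", "not_supportive"]
        assert evidences["st2"].sentences[0].pmid == "333"

    def test_missing_label_rejected(self, tmp_path):
        sub, labels = self._write(tmp_path)
        labels.write_text("st1\t1\tfully\n")
        with pytest.raises(ValueError, match="no label"):
            load_ranked_evidence(sub, labels)

    def test_wrong_column_count_names_line(self, tmp_path):
        sub, labels = self._write(tmp_path)
        sub.write_text("st1\t1\t111\n")
        with pytest.raises(ValueError, match="line 1"):
            load_ranked_evidence(sub, labels)

    def test_track_limit_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            _evidence("a", ["fully"] * 11)
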