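"""Cascade scoring of a prediction corpus against a gold corpus.

Six levels are scored: term, function, function-secondary, relation,
relation-secondary and full statement.  Counts are micro-averaged:
TP/FP/FN are summed over all evidence sentences before precision, recall
and F are computed (a macro option averages per-evidence scores instead).

Within one evidence unit, term/function/relation/statement fragments are
deduplicated (repeated identical fragments earn no extra credit) while
secondary function fragments keep their multiplicity.  Credit assignment
between gold and predicted fragments uses a maximum bipartite matching
under the level's equivalence predicate, so scores cannot depend on
input order when equivalence classes overlap.  Syntactically or
semantically invalid predicted statements are ignored entirely.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .bel_model import Statement, node_key, parse_statement, validate_statement
from .equivalence import (
    EquivalenceMap,
    functions_equivalent,
    relation_match_count,
    statements_equivalent,
    terms_equivalent,
)
from .fragmenter import (
    FragmentBundle,
    FunctionFragment,
    RelationFragment,
    fragment_statement,
)

__all__ = [
    "LEVELS",
    "MetricCounts",
    "MetricScores",
    "EvaluationReport",
    "match_fragments",
    "evaluate_corpus",
    "f_score",
    "precision_recall_f",
    "format_report",
    "format_percent",
]

LEVELS = ("term", "function", "function_secondary",
          "relation", "relation_secondary", "statement")

_LEVEL_TITLES = {
    "term": "Terms", "function": "Function",
    "function_secondary": "Function-Secondary", "relation": "Relation",
    "relation_secondary": "Relation-Secondary", "statement": "Statement",
}


@dataclass
class MetricCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MetricCounts") -> "MetricCounts":
        return MetricCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)

    def __iadd__(self, other: "MetricCounts") -> "MetricCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


@dataclass
class MetricScores:
    precision: float
    recall: float
    f_score: float


@dataclass
class EvaluationReport:
    counts: dict                     # level -> MetricCounts
    scores: dict                     # level -> MetricScores
    ignored_invalid: int
    no_correct_prediction_sentences: dict  # level -> count
    n_evidences: int
    macro: bool = False


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def precision_recall_f(c: MetricCounts) -> MetricScores:
    """P = tp/(tp+fp), R = tp/(tp+fn), F harmonic mean; 0 on empty denominators."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return MetricScores(p, r, f_score(p, r))


# ---------------------------------------------------------------------------
# fragment matching
# ---------------------------------------------------------------------------

def _default_predicate(fragment, equiv: Optional[EquivalenceMap], strict_tloc: bool):
    if isinstance(fragment, FunctionFragment):
        return lambda g, p: functions_equivalent(g, p, equiv, strict_tloc=strict_tloc)
    if isinstance(fragment, RelationFragment):
        return lambda g, p: relation_match_count(g, p, equiv) == 3
    if isinstance(fragment, Statement):
        return lambda g, p: statements_equivalent(g, p, equiv, strict_tloc=strict_tloc)
    return lambda g, p: terms_equivalent(g, p, equiv)


def match_fragments(gold: Sequence, pred: Sequence,
                    equiv: Optional[EquivalenceMap] = None, *,
                    strict_tloc: bool = False,
                    predicate: Optional[Callable] = None) -> MetricCounts:
    """TP = size of a maximum bipartite matching between gold and predicted
    fragments under the level's equivalence predicate; FN/FP are the
    unmatched remainders.  The predicate is inferred from the fragment
    type unless given explicitly."""
    gold = list(gold)
    pred = list(pred)
    if not gold or not pred:
        return MetricCounts(tp=0, fp=len(pred), fn=len(gold))
    if predicate is None:
        predicate = _default_predicate(gold[0], equiv, strict_tloc)
    adj = np.zeros((len(gold), len(pred)), dtype=bool)
    for i, g in enumerate(gold):
        for j, p in enumerate(pred):
            adj[i, j] = predicate(g, p)
    matching = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    tp = int((matching >= 0).sum())
    return MetricCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


# ---------------------------------------------------------------------------
# corpus evaluation
# ---------------------------------------------------------------------------

Corpus = Union[Mapping[str, Sequence], Sequence]


def _statements_by_evidence(corpus: Corpus, *, validate: bool):
    """Normalize a corpus to {evidence_id: [Statement, ...]}.

    Accepts a mapping of evidence_id -> statement lines/Statements, or a
    sequence of objects with .evidence_id and .statements (EvidenceRecord).
    Returns (by_evidence, n_invalid); invalid items are dropped only when
    validate=True, otherwise they raise.
    """
    items = []
    if isinstance(corpus, Mapping):
        for eid, stmts in corpus.items():
            for s in stmts:
                items.append((eid, s))
    else:
        for rec in corpus:
            for s in rec.statements:
                items.append((rec.evidence_id, s))

    by_evidence: dict = {}
    n_invalid = 0
    for eid, s in items:
        if isinstance(s, Statement):
            stmt = s
        else:
            if validate:
                report = validate_statement(s)
                if not report.valid:
                    n_invalid += 1
                    continue
            stmt = parse_statement(s)
        by_evidence.setdefault(eid, []).append(stmt)

    if isinstance(corpus, Mapping):
        for eid in corpus:
            by_evidence.setdefault(eid, [])
    else:
        for rec in corpus:
            by_evidence.setdefault(rec.evidence_id, [])
    return by_evidence, n_invalid


def _combine_bundles(bundles: Sequence[FragmentBundle]):
    """Merge per-statement fragments into per-evidence fragment pools."""
    terms = _dedup_by_key([t for b in bundles for t in b.terms], node_key)
    functions = _dedup_by_key([f for b in bundles for f in b.functions],
                              FunctionFragment.key)
    secondary = Counter(ft for b in bundles for ft in b.secondary_functions)
    relations = _dedup_by_key([b.relation for b in bundles], RelationFragment.key)
    statements = _dedup_by_key([b.statement for b in bundles],
                               lambda s: (node_key(s.subject), s.relation,
                                          node_key(s.object)))
    return terms, functions, secondary, relations, statements


def _dedup_by_key(items, key):
    seen = set()
    out = []
    for it in items:
        k = key(it)
        if k not in seen:
            seen.add(k)
            out.append(it)
    return out


def _secondary_counts(gold: Counter, pred: Counter) -> MetricCounts:
    tp = sum(min(n, pred.get(ft, 0)) for ft, n in gold.items())
    return MetricCounts(tp=tp, fp=sum(pred.values()) - tp, fn=sum(gold.values()) - tp)


def evaluate_corpus(gold: Corpus, pred: Corpus,
                    equiv: Optional[EquivalenceMap] = None, *,
                    strict_tloc: bool = False,
                    macro: bool = False) -> EvaluationReport:
    """Score a prediction corpus against gold at all six cascade levels.

    ``gold``/``pred`` are mappings evidence_id -> statement lines (or
    parsed Statements), or sequences of EvidenceRecord.  Invalid predicted
    statements are ignored and counted in ``ignored_invalid``; gold
    statements must be valid.  Predictions for evidence ids absent from
    gold contribute false positives and raise a warning.
    """
    gold_by_ev, _ = _statements_by_evidence(gold, validate=False)
    pred_by_ev, n_invalid = _statements_by_evidence(pred, validate=True)

    orphans = sorted(set(pred_by_ev) - set(gold_by_ev))
    if orphans:
        warnings.warn(
            f"{len(orphans)} prediction evidence id(s) absent from gold "
            f"(e.g. {orphans[0]!r}); counted as false-positive sources",
            stacklevel=2)

    totals = {lv: MetricCounts() for lv in LEVELS}
    no_correct = {lv: 0 for lv in LEVELS}
    per_ev_scores = {lv: [] for lv in LEVELS}

    for eid in sorted(set(gold_by_ev) | set(pred_by_ev)):
        g_bundles = [fragment_statement(s) for s in gold_by_ev.get(eid, [])]
        p_bundles = [fragment_statement(s) for s in pred_by_ev.get(eid, [])]
        g_terms, g_funcs, g_sec, g_rels, g_stmts = _combine_bundles(g_bundles)
        p_terms, p_funcs, p_sec, p_rels, p_stmts = _combine_bundles(p_bundles)

        ev_counts = {
            "term": match_fragments(g_terms, p_terms, equiv, strict_tloc=strict_tloc),
            "function": match_fragments(g_funcs, p_funcs, equiv, strict_tloc=strict_tloc),
            "function_secondary": _secondary_counts(g_sec, p_sec),
            "relation": match_fragments(g_rels, p_rels, equiv, strict_tloc=strict_tloc),
            "relation_secondary": match_fragments(
                g_rels, p_rels, equiv,
                predicate=lambda g, p: relation_match_count(g, p, equiv) >= 2),
            "statement": match_fragments(g_stmts, p_stmts, equiv, strict_tloc=strict_tloc),
        }
        for lv, c in ev_counts.items():
            totals[lv] += c
            if c.tp == 0 and c.tp + c.fn > 0:
                no_correct[lv] += 1
            if macro:
                per_ev_scores[lv].append(precision_recall_f(c))

    if macro:
        scores = {}
        for lv in LEVELS:
            ss = per_ev_scores[lv]
            if ss:
                scores[lv] = MetricScores(
                    float(np.mean([s.precision for s in ss])),
                    float(np.mean([s.recall for s in ss])),
                    float(np.mean([s.f_score for s in ss])))
            else:
                scores[lv] = MetricScores(0.0, 0.0, 0.0)
    else:
        scores = {lv: precision_recall_f(totals[lv]) for lv in LEVELS}

    return EvaluationReport(
        counts=totals, scores=scores, ignored_invalid=n_invalid,
        no_correct_prediction_sentences=no_correct,
        n_evidences=len(set(gold_by_ev) | set(pred_by_ev)),
        macro=macro)


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------

def format_percent(fraction: float) -> str:
    """Percent scale, two decimals, round half up (0.49596 -> '49.60')."""
    return str(Decimal(repr(fraction * 100)).quantize(Decimal("0.01"),
                                                      rounding=ROUND_HALF_UP))


def format_report(report: EvaluationReport) -> str:
    """Plain-text table, one row per level with columns F, P, R."""
    header = f"{'Level':<20} {'F':>8} {'P':>8} {'R':>8} {'TP':>6} {'FP':>6} {'FN':>6}"
    lines = [header, "-" * len(header)]
    for lv in LEVELS:
        s = report.scores[lv]
        c = report.counts[lv]
        lines.append(
            f"{_LEVEL_TITLES[lv]:<20} {format_percent(s.f_score):>8}"
            f" {format_percent(s.precision):>8} {format_percent(s.recall):>8}"
            f" {c.tp:>6} {c.fp:>6} {c.fn:>6}")
    lines.append(f"ignored invalid predictions: {report.ignored_invalid}")
    return "\n".join(lines)
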