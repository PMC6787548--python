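"""Evaluation of ranked evidence-sentence retrieval for BEL statements.

Given a statement, a retrieval system returns up to ten ranked evidence
sentences (the submitted runs returned at most five).  Each sentence is
manually graded *fully supportive* (the sentence alone suffices to curate
the statement), *partially supportive* (context sentences or background
knowledge are needed) or *not supportive*.  The module computes:

* micro precision under the *full* criterion (only fully supportive
  counts) and the *partial* criterion (fully or partially supportive),
* mean average precision (MAP) over statements, where a statement's AP
  averages precision at the ranks of its relevant retrieved sentences
  and is normalized by the number of relevant *retrieved* sentences
  (the corpus-wide number of relevant sentences is unknowable from
  manual grading of submissions alone, so relevant-retrieved is the
  denominator -- reported MAP values depend on this choice),
* Cohen's kappa for inter-annotator agreement on the grades,
* the linear score combiner used for ranking, a weighted sum of the
  entity-entity, function-entity and relation classifier probabilities
  with default weights 0.4 / 0.5 / 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

from sklearn.metrics import cohen_kappa_score

from .evaluator import MetricCounts

__all__ = [
    "LABELS",
    "CRITERIA",
    "SentenceJudgment",
    "RankedEvidence",
    "RankWeights",
    "ClassifierProbs",
    "RetrievalReport",
    "is_relevant",
    "micro_precision",
    "average_precision",
    "mean_average_precision",
    "cohen_kappa",
    "combine_ranking_score",
    "evaluate_retrieval",
    "load_ranked_evidence",
]

LABELS = ("fully", "partially", "not_supportive")
CRITERIA = ("full", "partial")

MAX_SENTENCES = 10  # track limit per statement


@dataclass(frozen=True)
class SentenceJudgment:
    pmid: str
    sentence: str
    label: str  # one of LABELS


@dataclass(frozen=True)
class RankedEvidence:
    """A statement's retrieved sentences in the system's ranked order."""

    statement_id: str
    sentences: Tuple[SentenceJudgment, ...]

    def __post_init__(self):
        if len(self.sentences) > MAX_SENTENCES:
            raise ValueError(
                f"{self.statement_id}: {len(self.sentences)} sentences exceed "
                f"the track limit of {MAX_SENTENCES}")


@dataclass(frozen=True)
class RankWeights:
    """Weights of the three ranking classifiers (entity-entity,
    function-entity, relation)."""

    w_ee: float = 0.4
    w_fe: float = 0.5
    w_r: float = 0.1


@dataclass(frozen=True)
class ClassifierProbs:
    p_ee: float
    p_fe: float
    p_r: float


@dataclass
class RetrievalReport:
    counts: dict          # criterion -> MetricCounts (tp/fp; fn unused)
    precision: dict       # criterion -> float
    map: dict             # criterion -> float
    statements_with_hit: dict  # criterion -> count
    n_statements: int
    n_sentences: int


def is_relevant(label: str, criterion: str) -> bool:
    """Fully supportive sentences satisfy both criteria; partially
    supportive ones only the partial criterion."""
    if criterion == "full":
        return label == "fully"
    if criterion == "partial":
        return label in ("fully", "partially")
    raise ValueError(f"unknown criterion {criterion!r}")


def micro_precision(evidences: Sequence[RankedEvidence],
                    criterion: str) -> Tuple[MetricCounts, float]:
    """TP/FP over all retrieved sentences and the pooled precision."""
    tp = fp = 0
    for ev in evidences:
        for s in ev.sentences:
            if is_relevant(s.label, criterion):
                tp += 1
            else:
                fp += 1
    if tp + fp == 0:
        warnings.warn("empty submission: precision reported as 0", stacklevel=2)
        return MetricCounts(), 0.0
    return MetricCounts(tp=tp, fp=fp), tp / (tp + fp)


def average_precision(ranked_labels: Iterable[bool]) -> float:
    """Mean of precision@k over the relevant ranks k, divided by the
    number of relevant items in the list; 0 when none is relevant."""
    flags = list(ranked_labels)
    hits = 0
    total = 0.0
    for k, rel in enumerate(flags, start=1):
        if rel:
            hits += 1
            total += hits / k
    return total / hits if hits else 0.0


def mean_average_precision(evidences: Sequence[RankedEvidence],
                           criterion: str) -> float:
    """Unweighted mean of per-statement AP; statements whose list holds
    no relevant sentence (including empty lists) contribute 0."""
    if not evidences:
        return 0.0
    aps = [average_precision(is_relevant(s.label, criterion) for s in ev.sentences)
           for ev in evidences]
    return sum(aps) / len(aps)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> Tuple[float, float]:
    """Cohen's kappa and the raw percent agreement between two labelings.

    kappa = (p_o - p_e) / (1 - p_e); when chance agreement is 1 (a single
    category on both sides) kappa is 1 for identical labelings.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(f"labeling lengths differ: {len(labels_a)} vs {len(labels_b)}")
    if not labels_a:
        raise ValueError("empty labelings")
    agreement = sum(a == b for a, b in zip(labels_a, labels_b)) / len(labels_a)
    if len(set(labels_a) | set(labels_b)) == 1:
        return 1.0, agreement
    kappa = float(cohen_kappa_score(list(labels_a), list(labels_b)))
    return kappa, agreement


def combine_ranking_score(p: ClassifierProbs,
                          w: RankWeights = RankWeights()) -> float:
    """score = w_ee * p_ee + w_fe * p_fe + w_r * p_r (monotone in each)."""
    return w.w_ee * p.p_ee + w.w_fe * p.p_fe + w.w_r * p.p_r


def evaluate_retrieval(evidences: Sequence[RankedEvidence]) -> RetrievalReport:
    """Full task-2 report under both supportiveness criteria."""
    counts, precision, map_, hits = {}, {}, {}, {}
    for crit in CRITERIA:
        counts[crit], precision[crit] = micro_precision(evidences, crit)
        map_[crit] = mean_average_precision(evidences, crit)
        hits[crit] = sum(
            any(is_relevant(s.label, crit) for s in ev.sentences)
            for ev in evidences)
    return RetrievalReport(
        counts=counts, precision=precision, map=map_,
        statements_with_hit=hits, n_statements=len(evidences),
        n_sentences=sum(len(ev.sentences) for ev in evidences))


# ---------------------------------------------------------------------------
# submission / label files
# ---------------------------------------------------------------------------

_LABEL_ALIASES = {
    "fully": "fully", "full": "fully", "fully_supportive": "fully",
    "partially": "partially", "partial": "partially",
    "partially_supportive": "partially",
    "not_supportive": "not_supportive", "not": "not_supportive",
    "no": "not_supportive", "none": "not_supportive",
}


def load_ranked_evidence(submission_path, labels_path) -> list:
    """Join a ranked submission with its manual relevance labels.

    Submission TSV: statement_id, rank, pmid, sentence.
    Label TSV: statement_id, rank, label (fully/partially/not_supportive).
    Every submitted (statement, rank) needs a label.
    """
    rows = _read_tsv(submission_path, 4, "submission")
    labels = {}
    for lineno, (sid, rank, label) in _read_tsv(labels_path, 3, "label"):
        canon = _LABEL_ALIASES.get(label.strip().lower())
        if canon is None:
            raise ValueError(f"label file line {lineno}: unknown label {label!r}")
        labels[(sid, int(rank))] = canon

    per_statement: dict = {}
    for lineno, (sid, rank, pmid, sentence) in rows:
        try:
            rank_i = int(rank)
        except ValueError:
            raise ValueError(f"submission line {lineno}: rank {rank!r} is not an integer") from None
        if (sid, rank_i) not in labels:
            raise ValueError(f"submission line {lineno}: no label for "
                             f"statement {sid!r} rank {rank_i}")
        per_statement.setdefault(sid, []).append(
            (rank_i, SentenceJudgment(pmid, sentence, labels[(sid, rank_i)])))

    out = []
    for sid, ranked in per_statement.items():
        ranked.sort(key=lambda t: t[0])
        out.append(RankedEvidence(sid, tuple(s for _, s in ranked)))
    return out


def _read_tsv(path, n_cols: int, what: str):
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh.read().splitlines(), start=1):
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != n_cols:
                raise ValueError(
                    f"{what} file line {lineno}: expected {n_cols} columns, got {len(cells)}")
            out.append((lineno, tuple(cells)))
    return out
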