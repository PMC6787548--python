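"""Seeded synthetic gold/prediction corpora with typed error injection.

The generator emulates a task-1 gold corpus over the seven track
namespaces and the restricted function inventory: every evidence record
carries one valid statement whose subject is a protein term and whose
object class, function rates and increases:decreases ratio default to
the proportions of the 2017 test corpus.  :func:`perturb` injects one
typed error per statement with a given probability and records exactly
what it did; :func:`expected_counts` converts that realized log into the
level-wise TP/FP/FN the cascade evaluator must produce -- derived purely
from the level semantics, without running any fragment matching -- so
agreement between the two is testable exactly, not statistically.

All entities within one statement are pairwise distinct, swapped-in
entities are globally fresh, and composed complexes have exactly two
unmodified members; these invariants are what make the per-statement
count deltas below exact.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .bel_model import (
    Entity,
    FunctionTerm,
    GENE_NAMESPACES,
    Node,
    Statement,
    Term,
    serialize_statement,
    validate_statement,
)
from .evaluator import LEVELS, MetricCounts
from .io_formats import EvidenceRecord

__all__ = [
    "ERROR_KINDS",
    "PerturbationSpec",
    "PerturbationEvent",
    "generate_corpus",
    "perturb",
    "expected_counts",
    "DEFAULT_FUNCTION_RATES",
    "DEFAULT_OBJECT_CLASSES",
]

ERROR_KINDS = (
    "entity_swap", "namespace_swap", "relation_flip", "subject_object_swap",
    "function_drop", "function_add", "abundance_change", "invalidate_syntax",
    "drop_statement",
)

#: per-term probability of each modifier function (2017 test corpus:
#: 79 act, 36 pmod, 10 tloc, 4 deg over 405 terms)
DEFAULT_FUNCTION_RATES = {"act": 79 / 405, "pmod": 36 / 405,
                          "tloc": 10 / 405, "deg": 4 / 405}

#: object-slot class mix (2017 test corpus term/function columns, with the
#: protein remainder after one protein subject per statement)
DEFAULT_OBJECT_CLASSES = {"p": 0.61, "a": 0.25, "bp": 0.11,
                          "path": 0.01, "complex": 0.02}

#: 2017 test corpus relationship ratio: 130 increases, 68 decreases
DEFAULT_INCREASES_FRACTION = 130 / 198

_GENE_NS_WEIGHTS = (("HGNC", 0.8), ("MGI", 0.1), ("EGID", 0.1))
_GOCC_LOCATIONS = ("cytoplasm", "nucleus", "plasma membrane",
                   "mitochondrion", "extracellular space")


@dataclass(frozen=True)
class PerturbationSpec:
    error_kind: str
    rate: float
    seed: int = 0

    def __post_init__(self):
        if self.error_kind not in ERROR_KINDS:
            raise ValueError(f"unknown error_kind {self.error_kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate {self.rate} outside [0, 1]")


@dataclass(frozen=True)
class PerturbationEvent:
    """What actually happened to one gold statement."""

    evidence_id: str
    kind: Optional[str]          # None: statement left untouched
    gold: Statement
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

def _build_vocab(vocab_size: int) -> dict:
    vocab = {
        "HGNC": [f"GENE{i}" for i in range(vocab_size)],
        "MGI": [f"Gene{i}mus" for i in range(vocab_size)],
        "EGID": [str(10000 + i) for i in range(vocab_size)],
        # every fifth chemical needs quoting, like CHEBI:"calcium(2+)"
        "CHEBI": [f"chem({i}+)" if i % 5 == 0 else f"chem{i}"
                  for i in range(vocab_size)],
        "GOBP": [f"synthetic process {i}" for i in range(vocab_size)],
        "MESHD": [f"Disease{i}" for i in range(vocab_size)],
    }
    return vocab


def _draw_entity(rng: random.Random, vocab: dict, namespace: str,
                 used: set) -> Entity:
    values = vocab[namespace]
    free = [v for v in values if (namespace, v) not in used]
    if not free:
        raise ValueError(
            f"vocabulary of namespace {namespace} too small to draw distinct entities")
    value = rng.choice(free)
    used.add((namespace, value))
    return Entity(namespace, value)


def _gene_namespace(rng: random.Random) -> str:
    u = rng.random()
    acc = 0.0
    for ns, w in _GENE_NS_WEIGHTS:
        acc += w
        if u < acc:
            return ns
    return _GENE_NS_WEIGHTS[-1][0]


def _maybe_wrap(rng: random.Random, term: Term, function_rates: dict) -> Node:
    u = rng.random()
    acc = 0.0
    for ftype, rate in function_rates.items():
        acc += rate
        if u < acc:
            if ftype == "pmod":
                return FunctionTerm("pmod", term, mod_type="P")
            if ftype == "tloc":
                if rng.random() < 0.7:
                    src, dst = rng.sample(_GOCC_LOCATIONS, 2)
                    return FunctionTerm("tloc", term,
                                        from_loc=Entity("GOCC", src),
                                        to_loc=Entity("GOCC", dst))
                return FunctionTerm("tloc", term)
            return FunctionTerm(ftype, term)
    return term


def _draw_class(rng: random.Random, probs: dict) -> str:
    u = rng.random()
    acc = 0.0
    for cls, p in probs.items():
        acc += p
        if u < acc:
            return cls
    return next(iter(probs))


def generate_corpus(n_statements: int, vocab_size: int = 60,
                    function_rates: Optional[dict] = None, seed: int = 0,
                    increases_fraction: float = DEFAULT_INCREASES_FRACTION,
                    object_class_probs: Optional[dict] = None,
                    ) -> List[EvidenceRecord]:
    """Generate ``n_statements`` evidence records, one valid statement each.

    Deterministic under ``seed``.  ``function_rates`` maps ftype to the
    per-protein-term wrap probability; all-zero rates yield bare terms.
    """
    if n_statements < 1:
        raise ValueError("n_statements must be >= 1")
    rng = random.Random(seed)
    vocab = _build_vocab(vocab_size)
    f_rates = DEFAULT_FUNCTION_RATES if function_rates is None else function_rates
    obj_probs = DEFAULT_OBJECT_CLASSES if object_class_probs is None else object_class_probs

    records = []
    for i in range(n_statements):
        used: set = set()
        subj_term = Term("p", _draw_entity(rng, vocab, _gene_namespace(rng), used))
        subject = _maybe_wrap(rng, subj_term, f_rates)

        cls = _draw_class(rng, obj_probs)
        if cls == "p":
            obj_term = Term("p", _draw_entity(rng, vocab, _gene_namespace(rng), used))
            obj: Node = _maybe_wrap(rng, obj_term, f_rates)
        elif cls == "a":
            obj = Term("a", _draw_entity(rng, vocab, "CHEBI", used))
        elif cls == "bp":
            obj = Term("bp", _draw_entity(rng, vocab, "GOBP", used))
        elif cls == "path":
            obj = Term("path", _draw_entity(rng, vocab, "MESHD", used))
        else:  # composed complex, two distinct unmodified protein members
            members = tuple(
                Term("p", _draw_entity(rng, vocab, _gene_namespace(rng), used))
                for _ in range(2))
            obj = Term("complex", members=members)

        relation = "increases" if rng.random() < increases_fraction else "decreases"
        stmt = Statement(subject, relation, obj,
                         evidence_id=f"BEL:2017{i:05d}")
        line = serialize_statement(stmt)
        assert validate_statement(line).valid, f"generator produced invalid {line!r}"
        records.append(EvidenceRecord(
            evidence_id=stmt.evidence_id, pmid=str(30000000 + i),
            sentence=f"Synthetic evidence sentence {i} for cascade scoring.",
            statements=[stmt]))
    return records


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------

class _Fresh:
    """Globally fresh replacement values, never colliding with the vocab."""

    def __init__(self):
        self.n = 0

    def value(self) -> str:
        self.n += 1
        return f"swapped{self.n}"


def _leaf_addresses(stmt: Statement):
    """Addressable leaf terms: (slot, member_index or None)."""
    out = []
    for slot in ("subject", "object"):
        node = getattr(stmt, slot)
        base = node
        while isinstance(base, FunctionTerm):
            base = base.inner
        if base.is_composed_complex:
            out.extend((slot, j) for j in range(len(base.members)))
        else:
            out.append((slot, None))
    return out


def _get_leaf(stmt: Statement, slot: str, member_idx) -> Term:
    base = getattr(stmt, slot)
    while isinstance(base, FunctionTerm):
        base = base.inner
    return base.members[member_idx] if member_idx is not None else base


def _replace_leaf(stmt: Statement, slot: str, member_idx, new_leaf: Term) -> Statement:
    def rebuild(node: Node) -> Node:
        if isinstance(node, FunctionTerm):
            return replace(node, inner=rebuild(node.inner))
        if member_idx is not None:
            members = list(node.members)
            members[member_idx] = new_leaf
            return replace(node, members=tuple(members))
        return new_leaf
    return replace(stmt, **{slot: rebuild(getattr(stmt, slot))})


def _slot_has_function(stmt: Statement, slot: str) -> bool:
    return isinstance(getattr(stmt, slot), FunctionTerm)


def _apply_error(kind: str, stmt: Statement, rng: random.Random,
                 fresh: _Fresh):
    """Returns (mutated statement | raw line | None, detail) or
    (stmt, {'skipped': kind}) when the error is inapplicable."""
    if kind == "entity_swap" or kind == "namespace_swap":
        leaves = _leaf_addresses(stmt)
        if kind == "namespace_swap":
            leaves = [a for a in leaves
                      if _get_leaf(stmt, *a).entity.namespace in GENE_NAMESPACES]
            if not leaves:
                return stmt, {"skipped": kind}
        slot, idx = rng.choice(leaves)
        leaf = _get_leaf(stmt, slot, idx)
        if kind == "entity_swap":
            new_entity = Entity(leaf.entity.namespace, fresh.value())
        else:
            others = sorted(GENE_NAMESPACES - {leaf.entity.namespace})
            new_entity = Entity(rng.choice(others), leaf.entity.value)
        mutated = _replace_leaf(stmt, slot, idx, replace(leaf, entity=new_entity))
        return mutated, {"slot": slot,
                         "under_complex": idx is not None,
                         "under_function": idx is None and _slot_has_function(stmt, slot)}

    if kind == "relation_flip":
        flipped = "decreases" if stmt.relation == "increases" else "increases"
        return replace(stmt, relation=flipped), {}

    if kind == "subject_object_swap":
        return replace(stmt, subject=stmt.object, object=stmt.subject), {}

    if kind == "function_drop":
        droppable = []
        for slot in ("subject", "object"):
            node = getattr(stmt, slot)
            depth = 0
            while isinstance(node, FunctionTerm):
                droppable.append((slot, depth, node.ftype))
                node = node.inner
                depth += 1
        if not droppable:
            return stmt, {"skipped": kind}
        slot, depth, ftype = rng.choice(droppable)

        def drop(node: Node, d: int) -> Node:
            if d == 0:
                return node.inner
            return replace(node, inner=drop(node.inner, d - 1))

        return replace(stmt, **{slot: drop(getattr(stmt, slot), depth)}), {"ftype": ftype}

    if kind == "function_add":
        for slot in ("subject", "object"):
            node = getattr(stmt, slot)
            if isinstance(node, Term) and not node.is_composed_complex \
                    and node.abundance == "p":
                wrapped = FunctionTerm("act", node)
                return replace(stmt, **{slot: wrapped}), {"slot": slot}
        return stmt, {"skipped": kind}

    if kind == "abundance_change":
        leaves = [a for a in _leaf_addresses(stmt)
                  if _get_leaf(stmt, *a).abundance == "p"]
        if not leaves:
            return stmt, {"skipped": kind}
        slot, idx = rng.choice(leaves)
        leaf = _get_leaf(stmt, slot, idx)
        mutated = _replace_leaf(stmt, slot, idx,
                                replace(leaf, abundance=rng.choice(("g", "r"))))
        return mutated, {}

    if kind == "invalidate_syntax":
        return serialize_statement(stmt)[:-1], {}  # unbalanced parenthesis

    if kind == "drop_statement":
        return None, {}

    raise ValueError(f"unknown error_kind {kind!r}")


def perturb(corpus: Sequence[EvidenceRecord],
            spec: Union[PerturbationSpec, Sequence[PerturbationSpec]],
            ) -> Tuple[Dict[str, List[str]], List[PerturbationEvent]]:
    """Derive a prediction corpus by injecting at most one typed error per
    statement (the first spec whose rate fires wins), plus the realized
    perturbation log.  Deterministic for a given (corpus, spec)."""
    specs = [spec] if isinstance(spec, PerturbationSpec) else list(spec)
    rng = random.Random(specs[0].seed if specs else 0)
    fresh = _Fresh()
    pred: Dict[str, List[str]] = {}
    log: List[PerturbationEvent] = []
    for rec in corpus:
        for stmt in rec.statements:
            kind = None
            for sp in specs:
                if rng.random() < sp.rate:
                    kind = sp.error_kind
                    break
            detail: dict = {}
            result: Union[Statement, str, None] = stmt
            if kind is not None:
                result, detail = _apply_error(kind, stmt, rng, fresh)
                if detail.get("skipped"):
                    kind = None
                    result = stmt
            lines = pred.setdefault(rec.evidence_id, [])
            if result is None:
                pass  # dropped statement: no predicted line
            elif isinstance(result, str):
                lines.append(result)
            else:
                lines.append(serialize_statement(result))
            log.append(PerturbationEvent(rec.evidence_id, kind, stmt, detail))
    return pred, log


# ---------------------------------------------------------------------------
# analytic expected counts
# ---------------------------------------------------------------------------

def _structure(stmt: Statement) -> Tuple[int, int]:
    """(number of term fragments, number of function nodes)."""
    terms = functions = 0
    for slot in (stmt.subject, stmt.object):
        node = slot
        while isinstance(node, FunctionTerm):
            functions += 1
            node = node.inner
        terms += len(node.members) + 1 if node.is_composed_complex else 1
    return terms, functions


def _zero() -> Dict[str, MetricCounts]:
    return {lv: MetricCounts() for lv in LEVELS}


def expected_counts(log: Sequence[PerturbationEvent]) -> Dict[str, MetricCounts]:
    """Level-wise TP/FP/FN implied by a realized perturbation log.

    Derived statement by statement from the cascade level semantics (see
    the table in docs/methods.md), assuming the generator's invariants
    (distinct entities per statement, fresh swap values, two-member
    unmodified complexes, one statement per evidence).
    """
    totals = _zero()

    def add(level, tp=0, fp=0, fn=0):
        totals[level] += MetricCounts(tp, fp, fn)

    for ev in log:
        n_terms, n_funcs = _structure(ev.gold)
        kind = ev.kind
        if kind is None or kind == "abundance_change":
            # abundance relaxation: p/g/r interchangeable for genes
            add("term", tp=n_terms)
            add("function", tp=n_funcs)
            add("function_secondary", tp=n_funcs)
            add("relation", tp=1)
            add("relation_secondary", tp=1)
            add("statement", tp=1)
        elif kind in ("entity_swap", "namespace_swap"):
            add("term", tp=n_terms - 1, fp=1, fn=1)
            if ev.detail["under_complex"]:
                # the sibling member keeps the complex term, the relation
                # slot and the whole statement correct
                add("function", tp=n_funcs)
                add("function_secondary", tp=n_funcs)
                add("relation", tp=1)
                add("relation_secondary", tp=1)
                add("statement", tp=1)
            else:
                if ev.detail["under_function"]:
                    add("function", tp=n_funcs - 1, fp=1, fn=1)
                else:
                    add("function", tp=n_funcs)
                add("function_secondary", tp=n_funcs)
                add("relation", fp=1, fn=1)           # 2 of 3 units correct
                add("relation_secondary", tp=1)
                add("statement", fp=1, fn=1)
        elif kind == "relation_flip":
            add("term", tp=n_terms)
            add("function", tp=n_funcs)
            add("function_secondary", tp=n_funcs)
            add("relation", fp=1, fn=1)               # 2 of 3 units correct
            add("relation_secondary", tp=1)
            add("statement", fp=1, fn=1)
        elif kind == "subject_object_swap":
            add("term", tp=n_terms)
            add("function", tp=n_funcs)
            add("function_secondary", tp=n_funcs)
            add("relation", fp=1, fn=1)               # only the type matches
            add("relation_secondary", fp=1, fn=1)
            add("statement", fp=1, fn=1)
        elif kind == "function_drop":
            add("term", tp=n_terms)
            add("function", tp=n_funcs - 1, fn=1)
            add("function_secondary", tp=n_funcs - 1, fn=1)
            add("relation", tp=1)
            add("relation_secondary", tp=1)
            add("statement", fp=1, fn=1)
        elif kind == "function_add":
            add("term", tp=n_terms)
            add("function", tp=n_funcs, fp=1)
            add("function_secondary", tp=n_funcs, fp=1)
            add("relation", tp=1)
            add("relation_secondary", tp=1)
            add("statement", fp=1, fn=1)
        elif kind in ("invalidate_syntax", "drop_statement"):
            add("term", fn=n_terms)
            add("function", fn=n_funcs)
            add("function_secondary", fn=n_funcs)
            add("relation", fn=1)
            add("relation_secondary", fn=1)
            add("statement", fn=1)
        else:
            raise ValueError(f"unknown error_kind {kind!r}")
    return totals
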