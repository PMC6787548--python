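"""Matching simplifications applied at every evaluation level.

Gene and protein identifiers from HGNC, Entrez (EGID) or the mouse
ortholog resource MGI are accepted interchangeably when an equivalence
table groups them; for those namespaces any of the abundances p()/g()/r()
is accepted.  A composed complex counts as correct when at least one of
its members is correct.  pmod() is compared on the modification type
only, and tloc() on its argument term only (a strict mode additionally
requires both GOCC locations to agree).

No ortholog table ships with the package: with an empty
:class:`EquivalenceMap`, matching degenerates to exact namespace+value
identity (abundance-relaxed for gene namespaces), which avoids baking in
a particular database release.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .bel_model import (
    Entity,
    FunctionTerm,
    GENE_ABUNDANCES,
    GENE_NAMESPACES,
    Node,
    Statement,
    Term,
)
from .fragmenter import FunctionFragment, RelationFragment

__all__ = [
    "EquivalenceMap",
    "load_equivalence_map",
    "entities_equivalent",
    "terms_equivalent",
    "functions_equivalent",
    "relation_match_count",
    "statements_equivalent",
]

_GENE_COLUMNS = ("HGNC", "EGID", "MGI")


class EquivalenceMap:
    """Disjoint groups of (namespace, value) gene identifiers.

    Built from rows of orthologous/cross-namespace identifiers; rows that
    share an identifier are merged transitively (union-find).
    """

    def __init__(self, groups: Iterable[Iterable[Entity]] = ()):
        self._group_of: dict = {}
        self._n_groups = 0
        for group in groups:
            self.add_group(group)

    def add_group(self, entities: Iterable[Entity]) -> None:
        keys = [e.key() for e in entities]
        existing = {self._group_of[k] for k in keys if k in self._group_of}
        if existing:
            gid = min(existing)
            # merge any previously distinct groups hit by this row
            if len(existing) > 1:
                for k, g in list(self._group_of.items()):
                    if g in existing:
                        self._group_of[k] = gid
        else:
            gid = self._n_groups
            self._n_groups += 1
        for k in keys:
            self._group_of[k] = gid

    def same_group(self, a: Entity, b: Entity) -> bool:
        ga = self._group_of.get(a.key())
        return ga is not None and ga == self._group_of.get(b.key())

    def __len__(self) -> int:
        return len(set(self._group_of.values()))

    def __contains__(self, entity: Entity) -> bool:
        return entity.key() in self._group_of


def load_equivalence_map(path) -> EquivalenceMap:
    """Read a TSV with header ``HGNC<tab>EGID<tab>MGI``; blank cells allowed."""
    emap = EquivalenceMap()
    with open(path, encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return emap
    header = [c.strip().upper() for c in lines[0].split("\t")]
    if header != list(_GENE_COLUMNS):
        raise ValueError(
            f"line 1: expected header {'/'.join(_GENE_COLUMNS)}, got {lines[0]!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(_GENE_COLUMNS):
            raise ValueError(f"line {lineno}: expected {len(_GENE_COLUMNS)} columns, got {len(cells)}")
        group = [Entity(ns, v.strip()) for ns, v in zip(_GENE_COLUMNS, cells) if v.strip()]
        if group:
            emap.add_group(group)
    return emap


def entities_equivalent(a: Entity, b: Entity, emap: Optional[EquivalenceMap] = None) -> bool:
    """Exact identity (case-canonicalized), or joint membership of one
    gene-identifier group.  Non-gene namespaces require exact equality."""
    if a.key() == b.key():
        return True
    if a.namespace in GENE_NAMESPACES and b.namespace in GENE_NAMESPACES and emap is not None:
        return emap.same_group(a, b)
    return False


def terms_equivalent(a: Term, b: Term, emap: Optional[EquivalenceMap] = None) -> bool:
    if a.is_composed_complex or b.is_composed_complex:
        if not (a.is_composed_complex and b.is_composed_complex):
            return False
        # one correct member suffices
        from .fragmenter import strip_to_term
        return any(
            terms_equivalent(strip_to_term(ma), strip_to_term(mb), emap)
            for ma in a.members for mb in b.members)
    if (a.abundance in GENE_ABUNDANCES and b.abundance in GENE_ABUNDANCES
            and a.entity.namespace in GENE_NAMESPACES
            and b.entity.namespace in GENE_NAMESPACES):
        return entities_equivalent(a.entity, b.entity, emap)
    return a.abundance == b.abundance and entities_equivalent(a.entity, b.entity, emap)


def functions_equivalent(a: FunctionFragment, b: FunctionFragment,
                         emap: Optional[EquivalenceMap] = None,
                         strict_tloc: bool = False) -> bool:
    if a.ftype != b.ftype:
        return False
    if a.ftype == "pmod" and a.mod_type != b.mod_type:
        return False
    if strict_tloc and a.ftype == "tloc":
        for la, lb in ((a.from_loc, b.from_loc), (a.to_loc, b.to_loc)):
            if (la is None) != (lb is None):
                return False
            if la is not None and not entities_equivalent(la, lb, emap):
                return False
    return terms_equivalent(a.inner, b.inner, emap)


def _slot_match(gold_terms, pred_terms, emap) -> bool:
    return any(terms_equivalent(g, p, emap) for g in gold_terms for p in pred_terms)


def relation_match_count(g: RelationFragment, p: RelationFragment,
                         emap: Optional[EquivalenceMap] = None) -> int:
    """How many of subject, relation type and object agree (0..3).

    A slot agrees when any gold term in it is equivalent to any predicted
    term in it.  3 == full relation credit; >= 2 == secondary credit.
    """
    count = 0
    if _slot_match(g.subject_terms, p.subject_terms, emap):
        count += 1
    if g.relation == p.relation:
        count += 1
    if _slot_match(g.object_terms, p.object_terms, emap):
        count += 1
    return count


def _nodes_equivalent(a: Node, b: Node, emap, strict_tloc: bool) -> bool:
    if isinstance(a, Term) and isinstance(b, Term):
        return terms_equivalent(a, b, emap)
    if isinstance(a, FunctionTerm) and isinstance(b, FunctionTerm):
        if a.ftype != b.ftype:
            return False
        if a.ftype == "pmod" and a.mod_type != b.mod_type:
            return False
        if strict_tloc and a.ftype == "tloc":
            for la, lb in ((a.from_loc, b.from_loc), (a.to_loc, b.to_loc)):
                if (la is None) != (lb is None):
                    return False
                if la is not None and not entities_equivalent(la, lb, emap):
                    return False
        return _nodes_equivalent(a.inner, b.inner, emap, strict_tloc)
    return False


def statements_equivalent(a: Statement, b: Statement,
                          emap: Optional[EquivalenceMap] = None,
                          strict_tloc: bool = False) -> bool:
    """Entire-statement correctness under the same simplifications."""
    return (a.relation == b.relation
            and _nodes_equivalent(a.subject, b.subject, emap, strict_tloc)
            and _nodes_equivalent(a.object, b.object, emap, strict_tloc))
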