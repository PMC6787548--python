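"""Decompose a statement into the fragments scored at each cascade level.

A full statement is cut into:

* **terms** -- every leaf abundance term; a composed complex contributes
  its member terms individually *and* the complex term itself,
* **functions** -- one fragment per modifier-function node, paired with
  the function-stripped term it modifies,
* **secondary functions** -- the bare function types, one per node
  (a multiset: repeated types keep their multiplicity),
* **relation** -- subject terms, relation type and object terms with all
  function wrappers removed,
* the **statement** itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .bel_model import (
    EMBEDDED_FUNCTIONS,
    FunctionTerm,
    Node,
    Statement,
    Term,
    node_key,
    serialize_node,
)

__all__ = [
    "FunctionFragment",
    "RelationFragment",
    "FragmentBundle",
    "strip_functions",
    "strip_to_term",
    "strip_wrappers",
    "fragment_statement",
]


@dataclass(frozen=True)
class FunctionFragment:
    """A modifier function together with its (stripped) argument term."""

    ftype: str                       # activity subtypes already collapsed to act
    inner: Term                      # function-stripped argument (may be a complex)
    mod_type: Optional[str] = None   # pmod only
    from_loc: object = None          # tloc only; compared in strict mode
    to_loc: object = None

    def key(self) -> tuple:
        return (self.ftype, self.mod_type, node_key(self.inner))


@dataclass(frozen=True)
class RelationFragment:
    """Function-stripped subject/object term sets plus the relation type."""

    subject_terms: frozenset
    relation: str
    object_terms: frozenset

    def key(self) -> tuple:
        return (frozenset(node_key(t) for t in self.subject_terms),
                self.relation,
                frozenset(node_key(t) for t in self.object_terms))


@dataclass
class FragmentBundle:
    terms: list                  # deduplicated leaf/complex Terms
    functions: list              # deduplicated FunctionFragments
    secondary_functions: list    # multiset of ftype strings
    relation: RelationFragment
    statement: Statement


def strip_to_term(node: Node) -> Term:
    """Peel every function wrapper off a node, returning the bare term."""
    while isinstance(node, FunctionTerm):
        node = node.inner
    return node


def strip_functions(node: Node) -> frozenset:
    """Leaf term set under any chain of wrappers; a composed complex
    yields its (stripped) members plus the complex term itself."""
    term = strip_to_term(node)
    if term.is_composed_complex:
        out = {strip_to_term(m) for m in term.members}
        out.add(strip_wrappers(term))
        return frozenset(out)
    return frozenset({term})


def strip_wrappers(node: Node) -> Term:
    """Like strip_to_term, but rebuilds complexes with stripped members."""
    term = strip_to_term(node)
    if term.is_composed_complex:
        return Term("complex", members=tuple(strip_to_term(m) for m in term.members))
    return term


def _function_nodes(node: Node) -> list:
    out = []
    while isinstance(node, FunctionTerm):
        out.append(node)
        node = node.inner
    if node.is_composed_complex:
        for m in node.members:
            out.extend(_function_nodes(m))
    return out


def _dedup(items, key):
    seen = set()
    out = []
    for it in items:
        k = key(it)
        if k not in seen:
            seen.add(k)
            out.append(it)
    return out


def fragment_statement(s: Statement) -> FragmentBundle:
    """Deterministically cut a statement into its cascade fragments."""
    terms = list(strip_functions(s.subject) | strip_functions(s.object))
    terms.sort(key=lambda t: serialize_node(t))

    fnodes = _function_nodes(s.subject) + _function_nodes(s.object)
    functions = []
    for fn in fnodes:
        functions.append(FunctionFragment(
            ftype=fn.ftype, inner=strip_wrappers(fn.inner), mod_type=fn.mod_type,
            from_loc=fn.from_loc, to_loc=fn.to_loc))
    functions = _dedup(functions, FunctionFragment.key)
    secondary = [fn.ftype for fn in fnodes]

    relation = RelationFragment(strip_functions(s.subject), s.relation,
                                strip_functions(s.object))
    return FragmentBundle(terms=terms, functions=functions,
                          secondary_functions=secondary,
                          relation=relation, statement=s)
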