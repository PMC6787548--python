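"""Data model, parser, serializer and validator for a restricted BEL dialect.

The dialect covers causal biomedical statements of the form

    subject relation object

where subject and object are namespaced abundance terms -- ``p()`` protein,
``a()`` chemical, ``bp()`` biological process, ``path()`` pathology,
``complex()`` protein complex, plus ``g()``/``r()`` gene and transcript
abundances -- optionally wrapped in the modifier functions ``act()``
(molecular activity), ``pmod(P)`` (phosphorylation), ``tloc()``
(translocation), ``deg()`` (degradation), ``sub()`` and ``trunc()``.
The two causal relation types are ``increases`` and ``decreases``
(``directly`` variants and the arrow symbols normalize onto them).

Entities live in seven controlled vocabularies: HGNC (human genes),
MGI (mouse genes), EGID (Entrez gene ids), CHEBI (chemicals), MESHD
(diseases), GOBP (biological processes) and GOCC (cellular components,
used for translocation endpoints).

Full BEL 1.0/2.0 (``reaction()``, ``fusion()``, nested statements,
sequence variants) is deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

__all__ = [
    "NAMESPACES",
    "GENE_NAMESPACES",
    "ABUNDANCES",
    "FUNCTIONS",
    "EMBEDDED_FUNCTIONS",
    "Entity",
    "Term",
    "FunctionTerm",
    "Statement",
    "ValidationReport",
    "ParseError",
    "parse_statement",
    "parse_term",
    "serialize_statement",
    "serialize_node",
    "serialize_entity",
    "validate_statement",
    "validate_node",
    "normalize_relation",
    "node_key",
]

NAMESPACES = frozenset({"HGNC", "MGI", "EGID", "CHEBI", "MESHD", "GOBP", "GOCC"})
GENE_NAMESPACES = frozenset({"HGNC", "MGI", "EGID"})

ABUNDANCES = frozenset({"p", "a", "bp", "path", "g", "r", "complex"})
#: gene/protein abundances are interchangeable during evaluation
GENE_ABUNDANCES = frozenset({"p", "g", "r"})

LONG_ABUNDANCES = {
    "proteinAbundance": "p",
    "abundance": "a",
    "biologicalProcess": "bp",
    "pathology": "path",
    "geneAbundance": "g",
    "rnaAbundance": "r",
    "complexAbundance": "complex",
}

FUNCTIONS = frozenset({"act", "pmod", "tloc", "deg", "sub", "trunc"})
#: functions spelled inside the argument list of a term: p(HGNC:ATF2, pmod(P))
EMBEDDED_FUNCTIONS = frozenset({"pmod", "sub", "trunc"})

LONG_FUNCTIONS = {
    "proteinModification": "pmod",
    "translocation": "tloc",
    "degradation": "deg",
    "substitution": "sub",
    "truncation": "trunc",
    "activity": "act",
}

#: which namespaces each abundance accepts; complex is unconstrained
ABUNDANCE_NAMESPACES = {
    "p": GENE_NAMESPACES,
    "g": GENE_NAMESPACES,
    "r": GENE_NAMESPACES,
    "a": frozenset({"CHEBI"}),
    "bp": frozenset({"GOBP"}),
    "path": frozenset({"MESHD"}),
}

_RELATIONS = {
    "increases": "increases",
    "directly increases": "increases",
    "->": "increases",
    "=>": "increases",
    "decreases": "decreases",
    "directly decreases": "decreases",
    "-|": "decreases",
    "=|": "decreases",
}

_PLAIN_VALUE = re.compile(r"[A-Za-z0-9_-]+")


class ParseError(ValueError):
    """Syntax error with the character offset where it was detected."""

    def __init__(self, position: int, message: str):
        super().__init__(f"position {position}: {message}")
        self.position = position
        self.message = message


def normalize_relation(token: str) -> str:
    """Map a relation word or arrow symbol onto increases/decreases."""
    canon = _RELATIONS.get(" ".join(token.split()))
    if canon is None:
        raise ValueError(f"unknown relation token {token!r}")
    return canon


# ---------------------------------------------------------------------------
# tree nodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Entity:
    """A namespaced identifier, e.g. HGNC:IL1B or CHEBI:"calcium(2+)"."""

    namespace: str
    value: str
    pos: int = field(default=0, compare=False)

    def key(self) -> tuple:
        """Canonical identity: namespace upper-cased; values compared
        case-insensitively except purely numeric identifiers."""
        v = self.value if self.value.isdigit() else self.value.casefold()
        return (self.namespace.upper(), v)


@dataclass(frozen=True)
class Term:
    """An abundance term: a named entity or a composed complex."""

    abundance: str
    entity: Optional[Entity] = None
    members: tuple = ()  # tuple[Node, ...], composed complex only
    pos: int = field(default=0, compare=False)

    @property
    def is_composed_complex(self) -> bool:
        return bool(self.members)


@dataclass(frozen=True)
class FunctionTerm:
    """A modifier function applied to a term (or another function)."""

    ftype: str                        # act, pmod, tloc, deg, sub, trunc
    inner: "Node"
    subtype: Optional[str] = None     # surface spelling, e.g. catalyticActivity
    mod_type: Optional[str] = None    # pmod modification type, "P"
    from_loc: Optional[Entity] = None
    to_loc: Optional[Entity] = None
    extra_args: tuple = ()            # retained verbatim, ignored for matching
    pos: int = field(default=0, compare=False)


Node = Union[Term, FunctionTerm]


@dataclass(frozen=True)
class Statement:
    subject: Node
    relation: str
    object: Node
    evidence_id: str = field(default="", compare=False)
    raw_text: str = field(default="", compare=False)


@dataclass
class ValidationReport:
    valid: bool
    errors: list  # list[tuple[int, str]]


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<punct>[(),:])
  | (?P<quoted>"[^"]*" | “[^“”]*”)
  | (?P<word>[^\s(),:"“”]+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list:
    tokens = []
    i = 0
    n = len(text)
    while i < n:
        m = _TOKEN.match(text, i)
        if m is None:  # stray quote character
            raise ParseError(i, f"unexpected character {text[i]!r}")
        if m.lastgroup == "punct":
            tokens.append((m.group(), m.group(), i))
        elif m.lastgroup == "quoted":
            tokens.append(("QUOTED", m.group()[1:-1], i))
        elif m.lastgroup == "word":
            tokens.append(("WORD", m.group(), i))
        i = m.end()
    tokens.append(("EOF", "", n))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    # -- token plumbing ----------------------------------------------------
    def peek(self, ahead: int = 0):
        j = min(self.i + ahead, len(self.tokens) - 1)
        return self.tokens[j]

    def next(self):
        tok = self.tokens[self.i]
        if tok[0] != "EOF":
            self.i += 1
        return tok

    def expect(self, kind: str, what: str):
        tok = self.next()
        if tok[0] != kind:
            raise ParseError(tok[2], f"expected {what}, got {tok[1]!r}" if tok[1] else f"expected {what}, got end of input")
        return tok

    # -- grammar -----------------------------------------------------------
    def parse_statement(self) -> Statement:
        subject = self.parse_node()
        relation = self.parse_relation()
        if self.peek()[0] == "EOF":
            raise ParseError(self.peek()[2], "missing object term")
        obj = self.parse_node()
        tok = self.peek()
        if tok[0] != "EOF":
            raise ParseError(tok[2], f"unexpected trailing input {tok[1]!r}")
        return Statement(subject, relation, obj, raw_text=self.text)

    def parse_relation(self) -> str:
        kind, word, pos = self.next()
        if kind != "WORD":
            raise ParseError(pos, "missing relation" if kind == "EOF" else f"expected relation, got {word!r}")
        if word == "directly" and self.peek()[0] == "WORD":
            word = word + " " + self.next()[1]
        try:
            return normalize_relation(word)
        except ValueError:
            raise ParseError(pos, f"unknown relation {word!r}") from None

    def parse_node(self) -> Node:
        kind, name, pos = self.next()
        if kind != "WORD":
            raise ParseError(pos, "expected a term or function name" if kind == "EOF" else f"expected a term or function name, got {name!r}")
        ab = LONG_ABUNDANCES.get(name, name if name in ABUNDANCES else None)
        if ab is not None:
            self.expect("(", "'('")
            return self._parse_abundance(ab, pos)
        ftype, subtype = _resolve_function(name)
        if ftype is not None:
            self.expect("(", "'('")
            if ftype in EMBEDDED_FUNCTIONS:
                raise ParseError(pos, f"{ftype}() must appear inside a term's argument list")
            return self._parse_function(ftype, subtype, pos)
        raise ParseError(pos, f"unknown function or abundance {name!r}")

    def _parse_abundance(self, ab: str, pos: int) -> Node:
        if ab == "complex" and self.peek()[0] == "WORD" and self.peek(1)[0] == "(":
            members = [self.parse_node()]
            while self.peek()[0] == ",":
                self.next()
                members.append(self.parse_node())
            self.expect(")", "')'")
            return Term("complex", members=tuple(members), pos=pos)
        entity = self._parse_entity()
        node: Node = Term(ab, entity, pos=pos)
        while self.peek()[0] == ",":
            self.next()
            node = self._parse_embedded(node)
        self.expect(")", "')'")
        return node

    def _parse_embedded(self, inner: Node) -> Node:
        kind, name, pos = self.next()
        ftype, subtype = _resolve_function(name) if kind == "WORD" else (None, None)
        if ftype not in EMBEDDED_FUNCTIONS:
            raise ParseError(pos, f"expected pmod/sub/trunc argument, got {name!r}")
        self.expect("(", "'('")
        args = []
        while self.peek()[0] in ("WORD", "QUOTED"):
            args.append(self.next()[1])
            if self.peek()[0] == ",":
                self.next()
        self.expect(")", "')'")
        mod_type = None
        extra = tuple(args)
        if ftype == "pmod":
            if not args:
                raise ParseError(pos, "pmod() requires a modification type")
            mod_type, extra = args[0], tuple(args[1:])
        return FunctionTerm(ftype, inner, subtype=subtype, mod_type=mod_type,
                            extra_args=extra, pos=pos)

    def _parse_function(self, ftype: str, subtype: Optional[str], pos: int) -> FunctionTerm:
        if self.peek()[0] == "WORD" and self.peek(1)[0] == ":":
            # bare entity shorthand, e.g. catalyticActivity(HGNC:XIAP):
            # read as an implicit protein abundance
            entity = self._parse_entity()
            inner: Node = Term("p", entity, pos=entity.pos)
        else:
            inner = self.parse_node()
        from_loc = to_loc = None
        extra = []
        while self.peek()[0] == ",":
            self.next()
            if ftype == "tloc" and self.peek()[0] == "WORD" and self.peek(1)[0] == ":":
                loc = self._parse_entity()
                if from_loc is None:
                    from_loc = loc
                elif to_loc is None:
                    to_loc = loc
                else:
                    raise ParseError(loc.pos, "tloc() takes at most two location arguments")
            else:
                tok = self.next()
                if tok[0] not in ("WORD", "QUOTED"):
                    raise ParseError(tok[2], f"unexpected argument {tok[1]!r}")
                extra.append(tok[1])
        self.expect(")", "')'")
        return FunctionTerm(ftype, inner, subtype=subtype, from_loc=from_loc,
                            to_loc=to_loc, extra_args=tuple(extra), pos=pos)

    def _parse_entity(self) -> Entity:
        kind, ns, pos = self.next()
        if kind != "WORD":
            raise ParseError(pos, f"expected a namespace prefix, got {ns!r}")
        if self.peek()[0] != ":":
            raise ParseError(self.peek()[2], f"expected ':' after namespace {ns!r}")
        self.next()
        canon = ns.upper()
        if canon not in NAMESPACES:
            raise ParseError(pos, f"unknown namespace {ns!r}")
        vkind, value, vpos = self.next()
        if vkind not in ("WORD", "QUOTED") or not value:
            raise ParseError(vpos, "missing entity value")
        return Entity(canon, value, pos=pos)


def _resolve_function(name: str):
    """Map a surface function name to (short ftype, retained subtype)."""
    if name in FUNCTIONS:
        return name, None
    if name in LONG_FUNCTIONS:
        return LONG_FUNCTIONS[name], (name if LONG_FUNCTIONS[name] == "act" and name != "activity" else None)
    if name.endswith("Activity") and len(name) > len("Activity"):
        return "act", name
    return None, None


# ---------------------------------------------------------------------------
# public parse / serialize / validate
# ---------------------------------------------------------------------------

def parse_statement(text: str) -> Statement:
    """Parse one candidate statement line into a Statement tree.

    Raises ParseError (with character position) on malformed input.
    Namespace/abundance compatibility is *not* enforced here; use
    :func:`validate_statement` for the full semantic check.
    """
    if not text or not text.strip():
        raise ParseError(0, "empty input")
    return _Parser(text).parse_statement()


def parse_term(text: str) -> Node:
    """Parse a single term or function expression."""
    if not text or not text.strip():
        raise ParseError(0, "empty input")
    p = _Parser(text)
    node = p.parse_node()
    tok = p.peek()
    if tok[0] != "EOF":
        raise ParseError(tok[2], f"unexpected trailing input {tok[1]!r}")
    return node


def serialize_entity(e: Entity) -> str:
    if _PLAIN_VALUE.fullmatch(e.value):
        return f"{e.namespace}:{e.value}"
    return f'{e.namespace}:"{e.value}"'


def _embedded_chain(node: Node):
    """Split pmod/sub/trunc wrappers off a term: returns (base, mods outside-in)."""
    mods = []
    while isinstance(node, FunctionTerm) and node.ftype in EMBEDDED_FUNCTIONS:
        mods.append(node)
        node = node.inner
    return node, mods


def serialize_node(node: Node) -> str:
    """Canonical spelling: short names, ', ' separators, straight quotes."""
    if isinstance(node, Term):
        if node.is_composed_complex:
            return "complex({})".format(", ".join(serialize_node(m) for m in node.members))
        return f"{node.abundance}({serialize_entity(node.entity)})"
    if node.ftype in EMBEDDED_FUNCTIONS:
        base, mods = _embedded_chain(node)
        if not (isinstance(base, Term) and base.entity is not None):
            raise ValueError(f"{node.ftype}() must modify a named term")
        rendered = []
        for m in reversed(mods):  # reversed == original argument order
            args = ((m.mod_type,) if m.mod_type else ()) + m.extra_args
            rendered.append("{}({})".format(m.ftype, ", ".join(args)))
        return "{}({}, {})".format(base.abundance, serialize_entity(base.entity),
                                   ", ".join(rendered))
    parts = [serialize_node(node.inner)]
    if node.ftype == "tloc":
        parts += [serialize_entity(loc) for loc in (node.from_loc, node.to_loc) if loc]
    parts += list(node.extra_args)
    return "{}({})".format("act" if node.ftype == "act" else node.ftype, ", ".join(parts))


def serialize_statement(s: Statement) -> str:
    return f"{serialize_node(s.subject)} {s.relation} {serialize_node(s.object)}"


def validate_node(node: Node, errors: list) -> None:
    """Append (position, message) records for every semantic violation."""
    if isinstance(node, Term):
        if node.is_composed_complex:
            if len(node.members) < 2:
                errors.append((node.pos, "composed complex() needs at least two members"))
            for m in node.members:
                validate_node(m, errors)
            return
        allowed = ABUNDANCE_NAMESPACES.get(node.abundance)
        if allowed is not None and node.entity.namespace not in allowed:
            errors.append((node.entity.pos,
                           "abundance {}() does not accept namespace {} (expects {})".format(
                               node.abundance, node.entity.namespace,
                               "/".join(sorted(allowed)))))
        return
    if node.ftype == "tloc":
        for loc in (node.from_loc, node.to_loc):
            if loc is not None and loc.namespace != "GOCC":
                errors.append((loc.pos, f"tloc() locations must be GOCC, got {loc.namespace}"))
    if node.ftype in EMBEDDED_FUNCTIONS:
        base, _ = _embedded_chain(node)
        if not (isinstance(base, Term) and base.entity is not None):
            errors.append((node.pos, f"{node.ftype}() must modify a named abundance term"))
    validate_node(node.inner, errors)


def validate_statement(text: str) -> ValidationReport:
    """Parse plus full semantic check; violations are data, not exceptions."""
    try:
        stmt = parse_statement(text)
    except ParseError as exc:
        return ValidationReport(False, [(exc.position, exc.message)])
    errors: list = []
    validate_node(stmt.subject, errors)
    validate_node(stmt.object, errors)
    return ValidationReport(not errors, errors)


# ---------------------------------------------------------------------------
# canonical identity keys (used for within-evidence deduplication)
# ---------------------------------------------------------------------------

def node_key(node: Node) -> tuple:
    """Hashable canonical identity of a node.

    Case differences in entity values, activity subtypes and retained
    extra arguments do not distinguish fragments; composed-complex member
    order is immaterial.
    """
    if isinstance(node, Term):
        if node.is_composed_complex:
            return ("complex", frozenset(node_key(m) for m in node.members))
        return ("term", node.abundance, node.entity.key())
    if node.ftype == "tloc":
        locs = tuple(e.key() if e else None for e in (node.from_loc, node.to_loc))
        return ("tloc", node_key(node.inner), locs)
    if node.ftype == "pmod":
        return ("pmod", node.mod_type, node_key(node.inner))
    return (node.ftype, node_key(node.inner))
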