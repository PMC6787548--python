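"""Readers and writers for the corpus interchange formats.

BioC dialect
------------
One ``<document>`` per evidence sentence.  The document id is the PMID;
the single ``<passage>`` carries an ``evidence_id`` infon, the sentence
as its ``<text>``, and one ``<annotation>`` per BEL statement with an
infon ``type=bel`` and the statement string as the annotation text.
The exact infon schema is this package's own dialect: the reader accepts
exactly what the writer emits, and round-trips are guaranteed up to
canonical statement spelling.

Tab-separated dialects
----------------------
* submission: ``evidence_id<TAB>statement`` (one statement per line),
* fragments: ``evidence_id<TAB>kind<TAB>text`` with kinds
  term/function/relation/statement,
* entity annotations: ``evidence_id<TAB>start<TAB>end<TAB>surface<TAB>
  namespace<TAB>concept`` with 0-based half-open *character* offsets.

All readers report the offending line number on malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from lxml import etree

from .bel_model import (
    NAMESPACES,
    ParseError,
    Statement,
    parse_statement,
    serialize_node,
    serialize_statement,
)
from .fragmenter import fragment_statement, strip_wrappers

__all__ = [
    "EvidenceRecord",
    "EntityAnnotation",
    "read_bioc_corpus",
    "write_bioc_corpus",
    "read_submission",
    "write_submission",
    "write_fragment_table",
    "read_entity_annotations",
]


@dataclass
class EvidenceRecord:
    """One evidence sentence with its (possibly empty) gold statements."""

    evidence_id: str
    pmid: str = ""
    sentence: str = ""
    statements: List[Statement] = field(default_factory=list)
    parse_errors: List[tuple] = field(default_factory=list)  # (raw text, message)


@dataclass(frozen=True)
class EntityAnnotation:
    evidence_id: str
    start: int
    end: int
    surface: str
    namespace: str
    concept: str


# ---------------------------------------------------------------------------
# BioC
# ---------------------------------------------------------------------------

def read_bioc_corpus(path) -> List[EvidenceRecord]:
    """Parse a BioC collection into evidence records.

    Statement strings that fail to parse are collected on the record's
    ``parse_errors`` instead of aborting the read.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed BioC XML: {exc}") from None
    root = tree.getroot()
    if root.tag != "collection":
        raise ValueError(f"malformed BioC XML: root element is <{root.tag}>, expected <collection>")
    records = []
    for doc in root.iter("document"):
        pmid = doc.findtext("id", default="")
        for passage in doc.iter("passage"):
            eid = None
            for infon in passage.findall("infon"):
                if infon.get("key") == "evidence_id":
                    eid = infon.text or ""
            if eid is None:
                path_desc = tree.getpath(passage)
                raise ValueError(f"passage {path_desc} lacks an evidence_id infon")
            rec = EvidenceRecord(evidence_id=eid, pmid=pmid,
                                 sentence=passage.findtext("text", default=""))
            for ann in passage.findall("annotation"):
                kinds = {i.get("key"): (i.text or "") for i in ann.findall("infon")}
                if kinds.get("type") != "bel":
                    continue
                raw = ann.findtext("text", default="")
                try:
                    rec.statements.append(parse_statement(raw))
                except ParseError as exc:
                    rec.parse_errors.append((raw, str(exc)))
            records.append(rec)
    return records


def write_bioc_corpus(records: Sequence[EvidenceRecord], path) -> None:
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = "belscore"
    for rec in records:
        doc = etree.SubElement(root, "document")
        etree.SubElement(doc, "id").text = rec.pmid
        passage = etree.SubElement(doc, "passage")
        infon = etree.SubElement(passage, "infon", key="evidence_id")
        infon.text = rec.evidence_id
        etree.SubElement(passage, "offset").text = "0"
        etree.SubElement(passage, "text").text = rec.sentence
        for i, stmt in enumerate(rec.statements):
            ann = etree.SubElement(passage, "annotation", id=str(i))
            etree.SubElement(ann, "infon", key="type").text = "bel"
            etree.SubElement(ann, "text").text = serialize_statement(stmt)
    etree.ElementTree(root).write(str(path), encoding="utf-8",
                                  xml_declaration=True, pretty_print=True)


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_submission(path) -> Dict[str, List[str]]:
    """Task-1 submission: evidence_id<TAB>statement.  Raw statement lines
    are preserved; parsing/validation is the evaluator's job.  Blank
    lines are skipped; LF and CRLF are both accepted."""
    out: Dict[str, List[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh.read().splitlines(), start=1):
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != 2:
                raise ValueError(f"line {lineno}: expected 2 tab-separated columns, got {len(cells)}")
            eid, stmt = cells
            out.setdefault(eid, []).append(stmt)
    return out


def write_submission(corpus: Mapping[str, Sequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for eid, stmts in corpus.items():
            for s in stmts:
                text = serialize_statement(s) if isinstance(s, Statement) else s
                fh.write(f"{eid}\t{text}\n")


_FRAGMENT_HEADER = "evidence_id\tkind\ttext"


def write_fragment_table(records: Sequence[EvidenceRecord], path) -> None:
    """Emit the tab-separated fragment rows of every statement: the leaf
    terms (complex members individually), one row per function node, the
    function-stripped relation and the full statement."""
    lines = [_FRAGMENT_HEADER]
    for rec in records:
        for stmt in rec.statements:
            bundle = fragment_statement(stmt)
            for t in bundle.terms:
                lines.append(f"{rec.evidence_id}\tterm\t{serialize_node(t)}")
            for f in bundle.functions:
                lines.append(f"{rec.evidence_id}\tfunction\t{_function_text(f)}")
            rel = "{} {} {}".format(serialize_node(strip_wrappers(stmt.subject)),
                                    stmt.relation,
                                    serialize_node(strip_wrappers(stmt.object)))
            lines.append(f"{rec.evidence_id}\trelation\t{rel}")
            lines.append(f"{rec.evidence_id}\tstatement\t{serialize_statement(stmt)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _function_text(frag) -> str:
    head = frag.ftype if frag.mod_type is None else f"{frag.ftype}({frag.mod_type})"
    return f"{head}[{serialize_node(frag.inner)}]"


def read_entity_annotations(path, corpus: Optional[Sequence[EvidenceRecord]] = None
                            ) -> List[EntityAnnotation]:
    """Stage-2 entity file; when a corpus is supplied, every offset span
    is checked against the evidence sentence."""
    sentences = {}
    if corpus is not None:
        sentences = {rec.evidence_id: rec.sentence for rec in corpus}
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh.read().splitlines(), start=1):
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != 6:
                raise ValueError(f"line {lineno}: expected 6 columns, got {len(cells)}")
            eid, start_s, end_s, surface, namespace, concept = cells
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"line {lineno}: offsets must be integers") from None
            if not (0 <= start < end):
                raise ValueError(f"line {lineno}: invalid span [{start}, {end})")
            ns = namespace.upper()
            if ns not in NAMESPACES:
                raise ValueError(f"line {lineno}: unknown namespace {namespace!r}")
            if eid in sentences:
                sent = sentences[eid]
                if end > len(sent) or sent[start:end] != surface:
                    raise ValueError(
                        f"line {lineno}: offsets [{start}, {end}) of evidence "
                        f"{eid!r} do not match surface {surface!r} "
                        f"(sentence has {sent[start:end]!r})")
            out.append(EntityAnnotation(eid, start, end, surface, ns, concept))
    return out
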