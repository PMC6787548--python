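"""Shared fixtures: published example statements, a small gene
equivalence table, and an exhaustive matching oracle."""

from __future__ import annotations

import pytest

from belscore import EquivalenceMap, Entity

#: statement strings printed in the track literature; all must parse
#: and validate (grammar closure)
PUBLISHED_STATEMENTS = [
    "p (HGNC:IL1B) increases p (HGNC:ATF2, pmod(P))",
    "act(p (HGNC:EDNRA)) increases a (CHEBI:“calcium(2+)”)",
    'act(p (HGNC:EDNRA)) increases a (CHEBI:"calcium(2+)")',
    "p (HGNC:TNF) increases tloc(p (HGNC:KHDRBS1), GOCC:cytoplasm, GOCC:nucleus)",
    "catalyticActivity (HGNC:XIAP) decreases catalyticActivity (HGNC:CASP9)",
    "p (MGI:Tmsb4x) decreases path (MESHD:Colitis)",
    "p (HGNC:CXCL8) increases p (HGNC:BCL2)",
]

FIG1_GOLD = "p (HGNC:IL1B) increases p (HGNC:ATF2, pmod(P))"
FIG1_CANONICAL = "p(HGNC:IL1B) increases p(HGNC:ATF2, pmod(P))"


@pytest.fixture
def gene_map() -> EquivalenceMap:
    """Human/Entrez/mouse ortholog groups for a handful of genes."""
    emap = EquivalenceMap()
    for hgnc, egid, mgi in [
        ("IL1B", "3553", "Il1b"),
        ("ATF2", "1386", "Atf2"),
        ("TNF", "7124", "Tnf"),
        ("GENE1", "10001", "Gene1mus"),
        ("GENE2", "10002", "Gene2mus"),
    ]:
        emap.add_group([Entity("HGNC", hgnc), Entity("EGID", egid),
                        Entity("MGI", mgi)])
    return emap


def brute_force_matching(gold, pred, predicate) -> int:
    """Maximum matching size by exhaustive enumeration (oracle)."""
    pred = list(pred)

    def rec(i, used):
        if i == len(gold):
            return 0
        best = rec(i + 1, used)
        for j, p in enumerate(pred):
            if j not in used and predicate(gold[i], p):
                used.add(j)
                best = max(best, 1 + rec(i + 1, used))
                used.remove(j)
        return best

    return rec(0, set())
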