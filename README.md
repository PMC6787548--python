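# belscore

Evaluation toolkit for **Biological Expression Language (BEL) relation
extraction**. Text-mining systems that read a biomedical sentence such as

> "IL-1β caused a time-dependent increase in Caco-2 ATF-2 phosphorylation…"

and emit a structured causal statement

```
p(HGNC:IL1B) increases p(HGNC:ATF2, pmod(P))
```

need a scorer that gives credit for partially correct output: a system
that found both proteins but flipped the causal direction is far more
useful to a curator than one that found nothing. `belscore` provides the
full evaluation stack for a restricted BEL dialect — for task organizers
building gold corpora, for system developers validating and scoring their
submissions, and for anyone who needs reproducible structured-prediction
metrics over BEL.

## What it implements

**Statement dialect.** Subject–relation–object triples over seven
namespaces (HGNC, MGI, EGID, CHEBI, MESHD, GOBP, GOCC), abundances
`p/g/r/a/bp/path/complex`, modifier functions `act()`, `pmod(P)`,
`tloc()`, `deg()`, `sub()`, `trunc()`, and the relations
`increases`/`decreases` (with `directly` variants and the arrow symbols
`->`, `=>`, `-|`, `=|` normalized onto them). The parser reports
position-tagged syntax errors; the validator additionally enforces
namespace–abundance compatibility (e.g. `bp()` only with GOBP).

**Cascade scoring.** Each statement is cut into fragments and scored at
six levels with micro-averaged precision *P = TP/(TP+FP)*, recall
*R = TP/(TP+FN)* and *F = 2PR/(P+R)*:

| level | credit for |
|---|---|
| term | each leaf abundance term |
| function | a function **with** its argument term |
| function-secondary | the function type alone |
| relation | subject, relation type and object all correct (functions stripped) |
| relation-secondary | two of the three units correct |
| statement | the entire statement |

Matching applies the track's simplifications: HGNC/EGID/MGI identifiers
grouped by an ortholog table are interchangeable, any of `p/g/r` is
accepted for genes, a composed complex is correct when one member is,
`pmod` compares the modification type only and `tloc` ignores its
location arguments (strict mode available). Credit is assigned by a
maximum bipartite matching so scores are order-independent; invalid
predicted statements are ignored.

**Evidence retrieval (task 2).** For ranked evidence-sentence retrieval:
micro support precision under a *fully supportive* and a *partially
supportive* criterion, mean average precision (MAP), Cohen's κ for
inter-annotator agreement, and the weighted ranking-score combiner
`score = 0.4·P_EE + 0.5·P_FE + 0.1·P_R`.

**I/O and fixtures.** BioC XML and TSV readers/writers, fragment-table
export, stage-2 entity-annotation files with offset checking, and a
seeded synthetic corpus generator that injects nine typed error kinds
(entity swap, relation flip, function drop, …) while predicting the
exact level-wise TP/FP/FN analytically — so the whole cascade is
testable without any external corpus.

## Worked example

```bash
belscore simulate --n 50 --seed 42 --error relation_flip --rate 0.3 \
    --out-gold g.tsv --out-pred p.tsv
belscore evaluate --gold g.tsv --pred p.tsv
```

```
Level                       F        P        R     TP     FP     FN
--------------------------------------------------------------------
Terms                  100.00   100.00   100.00    100      0      0
Function               100.00   100.00   100.00     31      0      0
Function-Secondary     100.00   100.00   100.00     31      0      0
Relation                60.00    60.00    60.00     30     20     20
Relation-Secondary     100.00   100.00   100.00     50      0      0
Statement               60.00    60.00    60.00     30     20     20
ignored invalid predictions: 0
```

Flipping the causal direction in 20 of 50 statements leaves every term
and function fragment correct (those levels stay at 100), costs exactly
those 20 statements at the relation and full-statement levels (30/50 =
60 %), and leaves relation-secondary perfect — two of three units
(subject and object) are still right, which is precisely the partial
credit that level exists to measure.

The same from Python:

```python
from belscore import evaluate_corpus, format_report

gold = {"ev1": ["p(HGNC:IL1B) increases p(HGNC:ATF2, pmod(P))"]}
pred = {"ev1": ["p(HGNC:IL1B) decreases p(HGNC:ATF2)"]}
print(format_report(evaluate_corpus(gold, pred)))
```

Both terms count as true positives; the dropped `pmod(P)` is a false
negative at both function levels; the flipped relation costs the
relation and statement levels but keeps secondary-relation credit.

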