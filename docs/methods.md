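# Methods

## The statement dialect

`belscore` evaluates a deliberately restricted BEL subset built for
relation-extraction benchmarking, not full BEL 1.0/2.0. A statement is
`subject relation object` with exactly two causal relation types;
`directly increases`/`directly decreases` and the arrow spellings
(`->`, `=>`, `-|`, `=|`) normalize to `increases`/`decreases` at parse
time. Terms are abundances over seven namespaces with fixed
compatibility: `a()` only with CHEBI, `bp()` only with GOBP, `path()`
only with MESHD, `p()/g()/r()` only with the gene namespaces
HGNC/MGI/EGID; `complex()` takes either a named entity or two or more
member terms. Modifier functions are `act()` (any `…Activity` long name
collapses to `act` for evaluation, the surface subtype is retained on
the node), `pmod(…)` with its modification type, `tloc()` with up to two
GOCC locations, `deg()`, and the rare `sub()`/`trunc()`, which parse and
validate but receive no special matching rule.

Parsing choices worth knowing:

- The parser is a hand-written tokenizer + recursive-descent grammar;
  every error carries the character offset where it was detected.
- Whitespace between a function name and `(` is tolerated (`p (HGNC:IL1B)`),
  and both straight and typographic double quotes are accepted on input;
  the canonical serializer always emits short function names, `", "`
  separators, no space before `(`, and straight quotes only when the
  value contains characters outside `[A-Za-z0-9_-]`.
- A bare namespaced entity directly inside a function, e.g.
  `catalyticActivity(HGNC:XIAP)`, is read as an implicit protein
  abundance and canonicalized to `act(p(HGNC:XIAP))`. This shorthand
  occurs in curated statements in the wild; accepting it keeps grammar
  closure over published examples.
- Parse success and semantic validity are separate: `bp(HGNC:TNF)` parses
  but fails validation with a namespace–abundance error. The evaluator
  treats both failure modes the same way (the prediction is ignored).

Identity for deduplication canonicalizes namespace case and compares
entity values case-insensitively unless they are purely numeric (Entrez
ids), where case is meaningless but digit identity is exact.

## Cascade scoring

Each statement is decomposed into fragments; per evidence sentence the
fragments of all its statements are pooled. Term, function, relation and
statement fragments are **deduplicated** within an evidence (a repeated
identical fragment earns nothing extra); secondary-function fragments
keep their **multiplicity** and are matched by per-type count minimum.
The asymmetry is intentional: the secondary function level measures "how
many function instances of each type did you find", which a set would
silently collapse whenever both slots of a statement carry the same
function type.

Matching credit at the term, function, relation and statement levels is
the size of a **maximum bipartite matching** between gold and predicted
fragments under that level's equivalence predicate
(`scipy.sparse.csgraph.maximum_bipartite_matching` on the boolean
compatibility matrix). A greedy assignment would be order-dependent as
soon as equivalence classes overlap — e.g. a predicted `g(EGID:…)` that
could pay for either of two gold terms through the ortholog table.
FN = |gold| − TP and FP = |valid predictions| − TP, so TP+FN and TP+FP
are conserved at every level.

Equivalence rules, all symmetric and reflexive:

- gene identifiers match exactly or through one group of the ortholog
  table (TSV with header `HGNC EGID MGI`, rows merged transitively);
  without a table, matching is exact identity — no database release is
  baked in;
- for gene namespaces any of `p/g/r` is accepted; other namespaces
  require the same abundance and exact entity;
- a composed complex matches another composed complex when at least one
  member pair matches (and never matches a plain term);
- functions require the same collapsed type and an equivalent argument
  term; `pmod` additionally compares the modification type (positions and
  amino acids are parsed but ignored); `tloc` ignores locations unless
  `strict_tloc` is set, in which case both GOCC endpoints must agree;
- a relation fragment scores one unit each for subject slot, relation
  type and object slot, slots matching any-vs-any over their
  function-stripped term sets (needed because a complex puts several
  terms into one slot); 3 units = relation credit, ≥ 2 = secondary
  credit;
- full-statement credit requires recursively equivalent subject and
  object trees and the same relation type.

Scores are micro-averaged: counts are summed over all evidences before
P, R and F are computed; `macro=True` averages per-evidence scores
instead. Reports print percentages with two decimals, rounded half-up,
matching the convention of published score tables. The per-level count
of evidences with gold fragments but zero true positives
(`no_correct_prediction_sentences`) is tracked for error analysis.

## Retrieval metrics

Support precision pools TP/FP over all submitted sentences of all
statements (micro). *Fully supportive* is a subset of *partially
supportive* by definition, so partial-criterion precision can never be
lower on the same labels. Average precision for one statement is the
mean of precision@k over the ranks k of its relevant retrieved
sentences, normalized by the number of relevant **retrieved** sentences;
MAP is the unweighted mean over all statements, and statements with an
empty or hit-less list contribute 0 rather than being dropped — omission
cannot raise the score. The normalization choice matters: the
corpus-wide number of relevant sentences is unknowable when only
submitted sentences are manually graded, so AP here is an upper bound on
the recall-normalized variant and MAP values are not comparable across
denominator conventions.

Cohen's κ is computed from the confusion table
(`sklearn.metrics.cohen_kappa_score`) and returned together with raw
percent agreement; when both annotators use a single category, chance
agreement is 1 and κ is defined as 1 for identical labelings. The
ranking combiner is the linear form `w_ee·p_ee + w_fe·p_fe + w_r·p_r`
with defaults (0.4, 0.5, 0.1); the weights sum to 1 by convention but
this is documented, not enforced.

## Synthetic fixtures

The generator emulates a task-1 gold corpus: one statement per evidence
record, subject always a protein term over a gene namespace (HGNC 80 %,
MGI and EGID 10 % each), object class drawn as p 0.61 / a 0.25 /
bp 0.11 / path 0.01 / complex 0.02, per-protein-term function rates
act 79/405, pmod 36/405, tloc 10/405, deg 4/405, and an
increases:decreases ratio of 130:68 — the proportions of the 2017 test
corpus composition, which is what the defaults are meant to resemble.
Within a statement all entities are pairwise distinct, complexes have
exactly two unmodified members, and swapped-in replacement entities are
globally fresh.

`perturb` injects at most one typed error per statement (the first spec
whose rate fires) and logs exactly what it did. `expected_counts` turns
that realized log into level-wise TP/FP/FN using only the level
semantics, never the matching machinery — e.g. an entity swap outside a
complex costs one term, turns the relation into a 2-of-3 (secondary
credit survives) and kills the statement, while the same swap inside a
two-member complex costs only the member term, because the sibling keeps
the complex term, the relation slot and the whole statement correct
under the one-correct-member rule. Using the realized log rather than
the nominal rate makes evaluator agreement an exact equality, not a
statistical test. An `abundance_change` (p→g/r on a gene) is the
deliberate null perturbation: it must change no count at any level,
which directly tests the abundance relaxation.

What the fixtures do **not** emulate: natural-language sentences, NER
offsets, multiple statements per sentence, duplicated fragments across
statements, near-miss entities that collide under an ortholog map, and
annotation noise. Passing the agreement suite therefore shows the
scoring semantics are implemented exactly as specified; it says nothing
about how hard real extraction is.

## Problem sizes and numerical choices

The test suite runs the full-rate agreement check at 60–120 statements
per error kind and 100 mixed-rate runs of 25 statements; the round-trip
identity uses 10 000 generated statements; the matching oracle compares
against exhaustive enumeration (feasible up to six fragments per side).
These sizes give exact, deterministic checks in seconds while covering
every code path; all randomness is seeded (`random.Random`, hypothesis
derandomized). Percent formatting uses `decimal` with ROUND_HALF_UP to
avoid binary-float rounding surprises at the printed two-decimal scale.

## Known limitations

- No nested statements (statement-as-object), `reaction()`, `fusion()`
  or sequence-variant syntax.
- The ortholog table must be supplied by the user; there is no bundled
  HGNC/MGI/Entrez snapshot.
- MAP depends on the relevant-retrieved normalization discussed above.
- The BioC dialect (passage infon `evidence_id`, annotation infon
  `type=bel`) is this package's own; other producers' BioC files may
  need key mapping before reading.
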