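# Methods

## The data model

The store is a miniature OBO-style phenotype ontology for a single
taxonomic domain (the fixtures use sedge, *Carex*-like, morphology).
Three root classes are seeded: an **anatomic-structure** root (annotated
equivalent to UBERON's *anatomical entity*), a **perceived-quality** root
(annotated as a subclass of PATO's *quality*) and a **new additions**
holding class. The holding class is itself a subclass of the
anatomic-structure root, so an author-contributed landmark term is
simultaneously "under new additions" (awaiting an ontology engineer's
re-filing via `reparent_term`) and an anatomic structure. External
anchors are stored as annotation strings only; nothing is resolved
remotely and no description-logic reasoning is attempted.

Identifiers are `CAREX:` plus a 7-digit zero-padded counter that only
moves forward. Nothing is ever deleted: terms and characters are
*deprecated*, keeping their id, axioms and history, so past usages remain
resolvable. Equivalence axioms are unordered pairs; the equivalence class
of an entity is the connected component of the axiom graph (computed with
networkx; the test suite cross-checks it against an independent
hand-written breadth-first traversal).

A **character** couples a parsed name, a five-field landmark method
(`from`/`to`/`include`/`exclude`/`at`), a unit, an ordered creator list,
a usage count and an append-only history. Characters live in the store as
subclasses of the perceived-quality root and are linked to the structure
terms their name mentions.

## Behavioural rules and the choices behind them

* **Name grammar.** Quality-first only: `<quality> of <structure>` or
  `<quality> between <structures>`. `between` takes two structures joined
  by `and`, or a single plural phrase; plurality is judged by a trailing
  *s* on the last word — crude, but transparent, and correct for the
  vocabulary this domain uses. The canonical rendering (lowercase, single
  spaces) is a parser fixed point.
* **Semantic check.** Method words are classified *known* (active term
  label, case-folded exact match), *new*, or ignorable (*stopword*:
  `of, a, an, the, to, from, at, and, or, between` — versioned in
  `config.py` — plus bare numbers). No stemming and no fuzzy matching: a
  plural word form is its own term, which is why the fixture ontology
  carries both `wing` and `wings`. Multi-word labels do not make their
  constituent words known.
* **Saving.** A character cannot be saved without a unit (seeded
  vocabulary `mm, cm, m, µm, count, ratio, degree`), without its method
  words being known, or — unless forced — under a name an active
  character already uses (the error lists the reuse candidates with
  creators and usage counts). A saved character needs either a method
  naming at least one of `from`/`to`/`at`, or at least one illustration
  reference; illustration-only definitions are legitimate (the study
  fixtures contain them) and this package treats illustrations as opaque
  string references.
* **Reuse.** `use_this` is the only operation that increments
  `usage_count`; every invocation counts, including repeat uses by the
  same actor. The invariant `usage_count == 1 + #used-events` is enforced
  by construction and property-tested. `clone_and_enhance` does **not**
  touch the source's usage count: the clone is a new character with its
  own count, shared creatorship (source creators plus the actor, order
  preserved) and an equivalence axiom to its source. Chains of clones
  therefore form growing equivalence classes. Concept drift along such
  chains is possible and deliberately not policed. Cloning inherits the
  unit unless explicitly changed; a clone without a text method inherits
  the source's illustrations.
* **Search.** Token containment (every content token of the query appears
  among the name's tokens), ranked by usage count descending, then name,
  then id. Usage-first ranking is an inference from how prominently usage
  information figures in reuse decisions; it is deterministic and easily
  replaced. Deprecated characters are excluded from search but remain
  retrievable by id.
* **Measurement table.** Columns may only reference saved, active
  characters; cells are single finite floats in the column character's
  unit, with negativity rejected for length-like units
  (`mm, cm, m, µm, count`). Overwrites keep per-cell history. Wide and
  long CSV exports agree on the multiset of (specimen, character, value);
  missing cells export as empty fields.

## Timestamps and determinism

Store timestamps come from a logical clock (a fixed 2018-09-01 UTC epoch
plus an event tick) rather than wall time. This makes every fixture a
pure function of `(seed, profile)` — byte-identical JSON on regeneration
— at the cost of timestamps that order events but do not date them. For a
single-user store this is the right trade; a multi-user deployment would
swap in real clocks.

Persistence is one JSON document (schema version 2). Loading applies
defaults for optional fields missing from older minor schema versions
(empty definition fields, empty illustration lists). OBO 1.4 and Turtle
exports are one-way.

## Evaluation metrics

* **Normalisation**: lowercase, punctuation stripped, whitespace split,
  pure-number tokens and stopwords removed; idempotent and
  order-preserving.
* **Unique definitions** are counted per 5-field tuple of normalised
  field texts (per-field counting is available behind a flag); unique
  words over the union of all five fields. Reduction percentages use
  `(before − after) / before × 100`.
* **Rounding** of all printed percentages is half away from zero — the
  convention that turns 87.5 into 88 and 93.75 into 94.
* **Likert**: mean and sample (n−1) standard deviation; agreement is the
  share scoring ≥ 4. The n−1 choice follows conventional survey
  reporting; sd is NaN for a single response.
* **Influence strength**: the weighted sum 3·strong + 2·some + 1·weak +
  0·none over respondent counts; linear in the counts.
* **Error accounting**: an error record carries categories
  `wrong_definition` and/or `wrong_unit`; `exclude_unit_only` discounts
  records whose *only* category is `wrong_unit` (interface slips, fixable
  by design, as opposed to knowledge errors — records with both
  categories remain counted).

## What the fixture generator emulates — and what it does not

`fixtures.make_fixture` rebuilds the study conditions: a home-grown sedge
ontology (~23 structure terms) and six preloaded characters differing in
usage count (one used 20 times vs. 2–5), creator persona ("Bruce Ford"
vs. the made-up "Yin Ming"), illustrations (0–2, some distractors) and
task match — including a distractor trio for the hardest task in which
two homonymous characters are illustration-only and one text-defined
character measures from the end of the perigynium wings to the summit of
the perigynium, including the beak teeth. The `individual` profile
carries everyday-object vocabulary instead.

`fixtures.make_experiment_tables` regenerates the evaluation inputs at
review-table granularity: machine-session error records whose counts per
(group, task, method, category) cell equal the published review tables,
paper-session review outcomes with the published per-task wrong counts,
and synthetic definition records whose paper-session vocabulary is
deliberately wider than the machine session's. The seed only shuffles
which synthetic participant carries which outcome; the marginals are
fixed by construction. What this does *not* emulate: real participants'
free-text wording (the synthetic definition pools show the convergence
direction, not the published unique-word totals, whose exact stopword
treatment is not recoverable), task timing, and any interaction-log
behaviour. Passing tests therefore demonstrate the arithmetic and the
data contracts, not human factors.

## Numerical and degenerate-input notes

* Counters and ticks are plain Python ints; no float identifiers.
* `reduction_percent` and `error_rate` reject non-positive denominators.
* Empty methods are vacuously `all_known`; an empty search query matches
  every active character (browse-all).
* Equivalence-axiom lists are kept sorted so store equality is structural
  and serialisation is canonical.
* Cycle checks on reparenting walk the ancestor chain; the subclass graph
  is validated acyclic on fixture load.

## Known limitations

* No OBO import, no RDF round-trip, no remote ontology alignment.
* Word-level semantic checking cannot recognise multi-word landmark
  phrases as units of meaning.
* The name grammar accepts at most two structures and one preposition; it
  has no noun-phrase parser and will reject valid but unusual phrasings.
* Illustrations are opaque references; nothing checks the files exist.
* Creator names are plain strings — no authentication, no identity
  resolution.

## Problem sizes used in tests

Property suites run on 100 seeded random stores of ≤100 entities each
(25–60 operations), 500 generated character names and 1000 generated
normalisation inputs; the full suite completes in a few seconds on one
CPU.
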