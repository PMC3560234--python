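# Methods

This note records the model implemented by `innomap`, the operational
definitions behind each derived quantity, the design choices made where the
underlying conceptual model is silent, and what the synthetic fixtures do and
do not establish.

## The three-axis model

A pharmaceutical innovation is described along three axes, each materialised
as a concept map (a rooted labeled tree) per indication:

1. **Medical context of use.** The condition treated, what the treatment
   targets (a disease, a symptom or a risk factor), the type of effect
   (curative, symptomatic, substitutive, preventive), required
   co-administrations, and the therapeutic arsenal — all marketed products
   sharing the indication, grouped by pharmacotherapeutic group.
2. **Nature of the novelty.** One mutually exclusive top-level category plus
   aspect flags (below).
3. **Impact versus a comparator.** Item-level verdicts in three dimensions —
   efficacy, safety, ease of use — each summarised as
   `impact / no_impact / not_assessable`.

Products with several indications get one set of maps per indication; the
classifier and comparator operate on one (product, arsenal/comparator) pair
at a time.

## Operational definitions

### Molecule identity and term matching

Two substances are the same molecule when both carry an ATC code and the
codes agree, otherwise when their normalized INNs are exactly equal.
Normalization is trim + case-fold + whitespace collapse and is idempotent.
There is no fuzzy or terminology-service matching anywhere: classification
must be deterministic and auditable from the input documents alone. The
consequence — two synonyms spelled differently are different terms — is a
deliberate trade of recall for reproducibility; callers who want
terminology reconciliation must apply it upstream.

### Novelty

With registry *R* (normalized molecule identifiers) and arsenal members
*M*:

* top level: `new_molecule` iff some substance ∉ *R*; else
  `new_combination` iff the product has ≥ 2 substances and its substance
  multiset (under molecule identity) matches no member; else
  `known_molecule`. The precedence makes the categories a partition, so
  tallies over a sample sum to the sample size; a combination containing a
  new molecule counts as a new molecule.
* mechanism / pharmacotherapeutic group: novel iff the product's normalized
  term is absent from the union of that attribute over *M*. The two flags
  are independent (they often co-occur; neither implies the other). The
  comparison frame is the arsenal, not the whole market — the only frame
  the input documents define.
* usage aspects: route and form carry scopes. The molecule scope compares
  against members sharing ≥ 1 substance (the natural reading of "novel for
  an existing molecule", extended to combinations by the shared-substance
  rule); the route scope (form only) against members sharing ≥ 1 route; the
  arsenal scope against all members. Dose (value + unit of one intake),
  presentation and protocol are molecule-scoped. The protocol is the dosing
  triple (dose per intake, intakes per day, duration of administration)
  compared as a unit — hence a new dose *implies* a new protocol, and the
  profile space excludes the combination (new dose, old protocol).
* `known_combination_new_form` is derived, not detected: top level
  `known_molecule` ∧ ≥ 2 substances ∧ form novel for the molecules.
* new indication / extension: some claimed condition term absent from the
  product line's previously approved labels (an input list; for a
  first-approval product the list is empty and the flag is trivially true).
* Attributes explicitly unknown (no stated dose, empty presentation) never
  claim novelty: a flag asserts a *new value*, which requires a value.

Every flag is an absent-from-a-membership-union test, so enlarging the
arsenal can only switch flags off (monotonicity). The one exception is the
derived `known_combination_new_form`, which can switch on when growth turns
a new combination into a known one; the property tests exclude it for that
reason.

### Impact

Verdicts are always from {positive, equivalent, negative, not_assessable}
and read from the new product's side.

* Safety term sets (serious ADRs, contraindications, serious DDIs) are
  compared by presence/absence, one item per term in the union. Direction
  convention: a term listed only for the new product is an *extra harm*
  (negative); only for the comparator, a harm avoided (positive). The
  convention is an artifact definition — the underlying comparison is pure
  presence/absence — but some direction is required to color the maps, and
  this one is conservative for the new product.
* Overdose: risk grade (low < moderate < high, lower better) and antidote
  availability (yes better) judged jointly; agreement in one and a tie in
  the other decides; opposite directions → not_assessable. Identical
  overdose blocks are equivalent even when unknown.
* Efficacy is an *input assertion* — a direction (superior / non_inferior /
  inferior / not_assessable) on one endpoint category (course of disease:
  cure, stabilization, remission; symptomatology; measurable parameter;
  prevention of occurrence or of complications) — never computed from trial
  data. Where no comparative trial exists the caller records
  not_assessable; expert conclusions enter as the asserted direction.
* Ease of use: patient items (units per intake, intakes per day, duration
  of administration — fewer/shorter better; invasiveness — lower better;
  convenience — a pre-graded ordinal input) and physician items (count of
  monitoring tests — fewer better; dose adjustability — pre-graded
  ordinal). Convenience and adjustability have no operational definition in
  the source documents; they are accepted only as pre-graded inputs and are
  not assessable when ungraded.
* Unknown handling: a value unknown on *one* side makes the item
  not_assessable; unknown on *both* sides it is equally unspecified and the
  item is equivalent. This keeps the two governing invariants
  simultaneously true: antisymmetry (swapping the products maps positive ↔
  negative, fixing equivalent and not_assessable) and self-comparison
  yielding only equivalent items with `no_impact` summaries.
* Dimension summary: `no_impact` iff every item is equivalent (vacuously
  for an empty dimension); otherwise `impact` if any item is decided, else
  `not_assessable`.

### Schema versions and the completeness scan

The record schema ships in two versions. `v2` (default) is the complete
model; `v1` lacks a single element — the duration of administration under
dosing/ease of use — and deliberately leaves its dosing object open, so an
unmodeled attribute in a document is not a parse failure but a *coverage
gap*. `schema_coverage(documents, version)` walks documents against the
schema and returns the dotted paths of populated attributes with no slot:
the machine analogue of reading a batch of SPCs against the model and
listing what it cannot represent. On the 20-record completeness sample the
v1 scan reports exactly `dosing.duration_days`; the v2 scan reports
nothing.

## Concept-map rendering

Fixed palette: product-specific #99CCFF (blue), positive #99FF99 (green),
equivalent #FFFF99 (yellow), negative #FF9999 (red); unhighlighted and
not-assessable nodes carry no color. The hex values are this package's
constants; only the color names are conventional. The novelty map always
renders the full aspect taxonomy and encodes the drug purely in the
highlighting, so maps of different drugs are structurally identical and
visually comparable. FreeMind output is pinned to map version 1.0.1
(nested `node` elements, `TEXT` attributes, `BACKGROUND_COLOR` for
highlights); import∘export is the identity on labels, child order and
highlights. DOT output is a digraph with one edge per parent-child pair.
Within a branch, children follow insertion order with alphabetical
ordering where the source is a set.

## Synthetic data

`generate_arsenal(config)` draws members over bounded per-attribute
vocabularies. Per attribute, a member reuses an earlier member's value with
the configured overlap probability (else draws uniformly from the
vocabulary), which controls arsenal homogeneity; defaults (3 members,
overlap 0.3, vocabularies of 6–30 values) give the small, moderately
homogeneous arsenals typical of one indication. Same seed, same arsenal,
byte for byte.

`generate_product_with_novelty(arsenal, target, seed)` inverts the
classifier constructively: composition from the target's top level, then
route, form, presentation, dosing and pharmacology chosen fresh or copied
from the appropriate comparison set so that each flag lands as requested.
Targets that violate the structural implications (new dose without new
protocol; arsenal-scope novelty without molecule-scope; flags requested
false where they are vacuously true, e.g. against an empty arsenal) raise
`UnsatisfiableTargetError` — the generator never returns a record that
classifies onto a different profile, since it verifies recovery before
returning.

The 40-record design sample and 20-record completeness sample encode only
*published aggregate compositions*; the per-drug attributes were never
published, so each record is a synthetic construction (typically an
attribute twin of an arsenal member with one controlled deviation) whose
classification contributes the right count. They are deterministic, contain
no real SPC content, and establish that the classifier reproduces the
aggregate composition from raw attributes — not that it reproduces any
real drug's classification. The worked-example records (prasugrel 10 mg
film-coated tablets versus clopidogrel 75 mg tablets; the epinephrine
auto-injector) use realistic compositions, indications and term shapes, but
their safety term sets are illustrative designed content: tests assert
structure and color logic over them, never medical facts.

What passing tests therefore show: the derivation engines implement the
stated definitions exactly (enumeration and oracle tests), behave lawfully
(monotonicity, antisymmetry, round-trips, recovery across ≥ 200 seeds), and
reproduce the known sample compositions from raw attributes. What they do
not show: performance on real SPC extracts, whose term variability
exact-match comparison does not absorb.

## Numerical and degenerate-input choices

* Strength/dose values compare by exact numeric equality (SPC strengths are
  printed discrete values; no tolerance is applied).
* Empty arsenals are legal: every union-based flag is then vacuously true
  and the context map's arsenal branch is empty.
* Validation never raises on bad content — it returns the full violation
  list with dotted paths — while document I/O raises `ParseError` on
  structural nonconformance; the two failure modes are deliberately
  distinct (a malformed document versus a well-formed record breaking a
  domain invariant).
* CLI output is canonical JSON (sorted keys, fixed indentation), so
  identical invocations are byte-identical and diffable.

## Known limitations

* Exact-match term comparison understates overlap between real SPCs written
  with different vocabularies; a terminology layer is upstream work.
* The "new pharmacotherapeutic group" frame is the arsenal, which may
  overstate group novelty for drugs whose group exists for other
  indications.
* Efficacy enters as one asserted direction per endpoint; conflicting
  trials must be reconciled by the caller.
* The degree of novelty (major/important/minor agency indices) and
  cost-effectiveness are out of scope by design.
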