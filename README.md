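# innomap

**Structured, objective description of pharmaceutical innovations.**

When a new manufactured drug product reaches the market, a physician needs to
answer three questions quickly: *what is it for* (the medical context of use),
*what is actually new about it* (against the therapeutic arsenal already
marketed for the indication), and *what difference does it make* (efficacy,
safety and ease of use versus a comparator). Monographs and agency evaluation
reports contain the raw material for these answers but bury it in prose.

`innomap` implements a three-axis conceptual model of pharmaceutical
innovation as typed, machine-checkable data plus two derivation engines:

* **Core model** — `ProductRecord` (a structured SPC extract: composition,
  form, routes, presentation, pharmacotherapeutic group, mechanism,
  indications, dosing, serious-ADR / contraindication / serious-DDI term
  sets, overdose risk, ease-of-use attributes) and `TherapeuticArsenal`
  (all products sharing an indication, with a known-molecule registry).
  JSON is the canonical document format (YAML accepted); published JSON
  Schemas in two model versions (`v1`/`v2`, differing only in the duration
  of administration).
* **Novelty classifier** — derives a `NoveltyProfile` by set computations
  against the arsenal: exactly one top-level category (precedence
  *new molecule* ≻ *new combination* ≻ *known molecule*), plus scoped flags
  for new mechanism of action, pharmacotherapeutic group, route, form,
  dose, presentation, protocol and new indication/extension. Formally, a
  product with substances *S* over registry *R* is a new molecule iff
  *S ⊄ R*; every aspect flag is an absent-from-membership-union test, so
  novelty is monotone: it can only shrink as the arsenal grows.
* **Impact comparator** — item-level `positive / equivalent / negative /
  not_assessable` verdicts versus one comparator. Safety term sets are
  differenced by presence/absence (a term listed only for the new product is
  an extra harm → negative); overdose combines the ordinal risk grade with
  antidote availability; efficacy is an asserted trial direction per
  endpoint category; ease of use covers patient burden (units, frequency,
  duration, invasiveness, convenience) and physician burden (monitoring,
  dose adjustability). All comparisons are antisymmetric.
* **Concept maps** — one rooted labeled tree per axis per indication, with
  the field's color conventions (blue = product-specific; green/yellow/red =
  positive/equivalent/negative), exported to FreeMind `.mm` XML, Graphviz
  DOT, or JSON.
* **Fixtures** — a seeded random-arsenal generator, a generator *inverse*
  (construct a product that classifies onto a requested profile, or fail
  loudly), and deterministic encoded samples: a 40-record model-design
  sample, a 20-record completeness sample, and the worked examples (a new
  antiplatelet tablet versus its comparator; an epinephrine auto-injector).

## Worked example

Materialise the epinephrine auto-injector fixture and classify it against an
arsenal of epinephrine ampoules:

```bash
innomap demo --fixture epipen --out demo/
innomap classify --product demo/epipen-product.json --arsenal demo/arsenal.json
```

```json
{
  "known_combination_new_form": false,
  "new_dose": false,
  "new_form": { "for_arsenal": false, "for_molecule": false, "for_route": false },
  "new_indication_or_extension": true,
  "new_mechanism_of_action": false,
  "new_pharmacotherapeutic_group": false,
  "new_presentation": true,
  "new_protocol": false,
  "new_route": { "for_arsenal": false, "for_molecule": false },
  "top_level": "known_molecule"
}
```

Read: epinephrine is a *known molecule* — same route, form, dose and
protocol as the marketed ampoules — and the whole novelty lies in the model
of injector (`new_presentation: true`). (Pass `--prior-labels` with the
previously approved labels to ground the indication flag; without it every
indication counts as new.)

Tallying the 40-record design sample partitions it across the three
top-level categories:

```bash
innomap demo --fixture design --out design/
innomap tally --profiles design/design-profiles.json
```

```json
{
  "top_level": { "known_molecule": 24, "new_combination": 5, "new_molecule": 11 },
  "n": 40,
  "flags": { "new_mechanism_of_action": 8, "new_pharmacotherapeutic_group": 8,
             "new_indication_or_extension": 14, "...": "..." }
}
```

11 new molecules (8 with a new mechanism of action and a new
pharmacotherapeutic group), 5 new combinations, 24 known molecules of which
14 carry a new indication or an extension. Rendering a concept map:

```bash
innomap render --axis impact --format mm \
    --new demo/efient-product.json --comparator demo/plavix-product.json \
    --evidence demo/evidence.json --out impact.mm
```

produces a FreeMind mind map whose leaves are colored green/yellow/red by
verdict; `--format dot` gives the same tree as a Graphviz digraph.

## Scope

No NLP extraction from SPC or report prose, no adjudication of ADR
seriousness (terms arrive pre-flagged), no cost-effectiveness, no national
novelty indices, and no vaccines or diagnostic agents. See
`docs/methods.md` for the model's assumptions and limitations.
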