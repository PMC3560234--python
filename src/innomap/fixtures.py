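"""Synthetic arsenals, a generator inverse for the novelty classifier, and
encoded study fixtures.

Three kinds of test data live here:

* :func:`generate_arsenal` — random therapeutic arsenals over bounded
  attribute vocabularies with controllable attribute overlap, reproducible
  by seed.
* :func:`generate_product_with_novelty` — the *inverse* of the novelty
  classifier: given an arsenal and a target :class:`NoveltyProfile`, it
  constructs raw product attributes that the classifier maps back onto
  exactly that profile, or raises :class:`UnsatisfiableTargetError` when no
  such product can exist for the arsenal (never a silently wrong record).
* Encoded fixtures: the two drug samples used to design the model and to
  analyse its completeness (40 and 20 records), and the worked example of a
  new antiplatelet product (Efient, prasugrel 10 mg) assessed against its
  comparator (Plavix, clopidogrel 75 mg) plus the auto-injector presentation
  example (Epipen, epinephrine).

The per-drug attributes of the 40- and 20-drug samples were never published;
those fixtures are synthetic records engineered so that the classifier's
*aggregate* tallies reproduce the samples' printed composition.  They are
deterministic (no randomness) and must never be mistaken for real SPC data.
The Efient/Plavix safety term sets are likewise illustrative designed
content: realistic in shape, asserted only for structure and color logic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .impact import EfficacyEvidence
from .model import (
    ContractError,
    Dosing,
    Indication,
    Overdose,
    ProductRecord,
    Substance,
    TherapeuticArsenal,
    normalize_term,
    validate_arsenal,
    validate_product,
)
from .novelty import NoveltyProfile, summarize_novelty

__all__ = [
    "CaseTriple",
    "EfientFixture",
    "EpipenFixture",
    "GeneratorConfig",
    "UnsatisfiableTargetError",
    "completeness_fixture",
    "design_sample_fixture",
    "efient_fixture",
    "epipen_fixture",
    "generate_arsenal",
    "generate_product_with_novelty",
]


class UnsatisfiableTargetError(ValueError):
    """No product over this arsenal can carry the requested novelty
    profile."""


# ---------------------------------------------------------------------------
# Random arsenal generation

_OVERLAP_ATTRS = ("route", "form", "presentation", "mechanism", "group")
_DEFAULT_VOCAB = {
    "inn": 30,
    "route": 6,
    "form": 8,
    "presentation": 8,
    "mechanism": 10,
    "group": 8,
    "adr": 12,
    "contraindication": 10,
    "ddi": 10,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random-arsenal generator.

    ``overlap_probabilities`` gives, per attribute, the probability that a
    member reuses the attribute value of an earlier member instead of drawing
    a fresh one from the vocabulary; it controls how homogeneous the arsenal
    looks.
    """

    seed: int = 0
    n_members: int = 3
    vocab_sizes: dict = field(default_factory=dict)
    overlap_probabilities: dict = field(default_factory=dict)
    n_extra_registry: int = 2

    def vocab(self, attr: str) -> int:
        return self.vocab_sizes.get(attr, _DEFAULT_VOCAB[attr])

    def overlap(self, attr: str) -> float:
        return self.overlap_probabilities.get(attr, 0.3)


def _check_config(config: GeneratorConfig) -> None:
    if config.n_members < 0:
        raise ContractError("n_members must be non-negative")
    if config.n_extra_registry < 0:
        raise ContractError("n_extra_registry must be non-negative")
    for attr in _DEFAULT_VOCAB:
        if config.vocab(attr) < 1:
            raise ContractError(f"vocab size for {attr!r} must be positive")
    for attr, p in config.overlap_probabilities.items():
        if not 0.0 <= p <= 1.0:
            raise ContractError(f"overlap probability for {attr!r} must be in [0, 1]")


def generate_arsenal(config: GeneratorConfig) -> TherapeuticArsenal:
    """Random validated arsenal over bounded vocabularies; identical seeds
    give identical arsenals."""
    _check_config(config)
    rng = random.Random(config.seed)
    vocab = {
        attr: [f"{attr}-{i:02d}" for i in range(config.vocab(attr))]
        for attr in _DEFAULT_VOCAB
    }
    indication = Indication(
        condition_term=f"condition-{config.seed % 100:02d}",
        target_kind="disease",
        treatment_type="curative",
    )
    members: list[ProductRecord] = []
    chosen: dict[str, list[str]] = {attr: [] for attr in _OVERLAP_ATTRS}
    used_inns: list[str] = []
    for j in range(config.n_members):
        attrs = {}
        for attr in _OVERLAP_ATTRS:
            if chosen[attr] and rng.random() < config.overlap(attr):
                attrs[attr] = rng.choice(chosen[attr])
            else:
                attrs[attr] = rng.choice(vocab[attr])
            chosen[attr].append(attrs[attr])
        inn = rng.choice(vocab["inn"])
        used_inns.append(inn)
        strength = rng.choice([1.0, 2.0, 5.0, 10.0, 20.0])
        member = ProductRecord(
            brand_name=f"member-{config.seed}-{j:02d}",
            substances=[
                Substance(
                    inn_name=inn,
                    strength_value=strength,
                    strength_unit="mg",
                )
            ],
            pharmaceutical_form=attrs["form"],
            routes={attrs["route"]},
            presentation_term=attrs["presentation"],
            pharmacotherapeutic_group=attrs["group"],
            mechanism_term=attrs["mechanism"],
            indications=[replace(indication)],
            dosing=Dosing(
                dose_per_intake_value=strength,
                dose_per_intake_unit="mg",
                intakes_per_day=float(rng.choice([1, 2, 3])),
                units_per_intake=1,
            ),
            serious_adr_terms=set(rng.sample(vocab["adr"], 2)),
            contraindication_terms=set(rng.sample(vocab["contraindication"], 2)),
            serious_ddi_terms=set(rng.sample(vocab["ddi"], 1)),
            overdose=Overdose(
                risk_grade=rng.choice(["low", "moderate", "high"]),
                antidote_available=rng.choice(["yes", "no"]),
            ),
            invasiveness_grade=rng.choice(["noninvasive", "minimally_invasive"]),
            convenience_grade="medium",
            dose_adjustability_grade="moderate",
        )
        members.append(member)
    registry = {normalize_term(i) for i in used_inns}
    registry.update(f"registry-extra-{k:02d}" for k in range(config.n_extra_registry))
    arsenal = TherapeuticArsenal(
        indication=indication, members=members, known_molecule_registry=registry
    )
    problems = validate_arsenal(arsenal)
    assert not problems, problems  # generator contract: output always valid
    return arsenal


# ---------------------------------------------------------------------------
# Generator inverse of the classifier


def _fresh(base: str, taken: set[str]) -> str:
    k = 0
    while f"{base}-{k:02d}" in taken:
        k += 1
    return f"{base}-{k:02d}"


def generate_product_with_novelty(
    arsenal: TherapeuticArsenal,
    target: NoveltyProfile,
    seed: int = 0,
    combination: bool | None = None,
) -> tuple[ProductRecord, list[Indication]]:
    """Construct ``(record, prior_labels)`` whose classification over
    ``arsenal`` recovers ``target`` exactly.

    ``combination`` forces a multi-substance composition for
    ``known_molecule`` targets (a marketed combination re-dosed, say);
    by default a combination is used only when the target requires one.
    Raises :class:`UnsatisfiableTargetError` when the target cannot be
    realised over this arsenal — e.g. a flag that is vacuously true cannot
    be requested false, and a new dose forces a new protocol.
    """
    rng = random.Random(seed)
    t = target
    members = arsenal.members
    registry = set(arsenal.known_molecule_registry)

    def unsat(msg: str):
        raise UnsatisfiableTargetError(msg)

    # Structural implications of the flag semantics.
    if t.new_dose and not t.new_protocol:
        unsat("a new dose is part of the protocol triple: new_dose implies new_protocol")
    if t.new_route.for_arsenal and not t.new_route.for_molecule:
        unsat("a route unused in the whole arsenal is unused for the molecule")
    if t.new_form.for_arsenal and not (t.new_form.for_molecule and t.new_form.for_route):
        unsat("a form unused in the whole arsenal is unused at every scope")
    if t.known_combination_new_form:
        if t.top_level != "known_molecule" or not t.new_form.for_molecule:
            unsat(
                "known_combination_new_form requires a marketed combination in a "
                "form new for its molecules"
            )
        combination = True
    elif (
        t.top_level == "known_molecule"
        and t.new_form.for_molecule
        and combination
    ):
        unsat(
            "a marketed combination in a new form would set "
            "known_combination_new_form"
        )

    member_routes_all = {normalize_term(r) for m in members for r in m.routes}
    member_forms_all = {normalize_term(m.pharmaceutical_form) for m in members}

    # --- composition -------------------------------------------------------
    substances: list[Substance]
    if t.top_level == "new_molecule":
        needs_sharing = not (t.new_route.for_molecule and t.new_form.for_molecule)
        inn = _fresh("novel-molecule", registry)
        substances = [Substance(inn_name=inn, strength_value=1.0, strength_unit="mg")]
        if needs_sharing:
            if not members:
                unsat("molecule-scoped flags are vacuously true over an empty arsenal")
            anchor = rng.choice(members)
            substances.append(replace(anchor.substances[0]))
    elif t.top_level == "new_combination":
        pool: dict[str, Substance] = {}
        for m in members:
            for s in m.substances:
                pool.setdefault(normalize_term(s.inn_name), replace(s))
        for name in sorted(registry):
            pool.setdefault(
                name, Substance(inn_name=name, strength_value=1.0, strength_unit="mg")
            )
        names = sorted(pool)
        if len(names) < 2:
            unsat("a new combination needs at least two known molecules")
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        rng.shuffle(pairs)
        substances = []
        for a, b in pairs:
            candidate = [pool[a], pool[b]]
            probe = ProductRecord(
                brand_name="probe", substances=candidate,
                pharmaceutical_form="x", routes={"x"}, presentation_term="",
                pharmacotherapeutic_group="", mechanism_term="",
                indications=[replace(arsenal.indication)],
            )
            if not any(probe.same_composition(m) for m in members):
                substances = candidate
                break
        if not substances:
            unsat("every pair of known molecules is already marketed together")
    else:  # known_molecule
        if combination:
            combos = [m for m in members if m.is_combination]
            if not combos:
                unsat("no marketed combination exists in the arsenal")
            anchor = rng.choice(combos)
            substances = [replace(s) for s in anchor.substances]
        elif members:
            anchor = rng.choice(members)
            substances = [replace(anchor.substances[0])]
        elif registry:
            if not (t.new_route.for_molecule and t.new_form.for_molecule):
                unsat("molecule-scoped flags are vacuously true over an empty arsenal")
            substances = [
                Substance(
                    inn_name=sorted(registry)[0],
                    strength_value=1.0,
                    strength_unit="mg",
                )
            ]
        else:
            unsat("a known molecule needs a non-empty registry")

    probe = ProductRecord(
        brand_name="probe", substances=substances,
        pharmaceutical_form="x", routes={"x"}, presentation_term="",
        pharmacotherapeutic_group="", mechanism_term="",
        indications=[replace(arsenal.indication)],
    )
    sharing = [m for m in members if probe.shares_substance(m)]
    sharing_routes = {normalize_term(r) for m in sharing for r in m.routes}

    # --- route -------------------------------------------------------------
    if t.new_route.for_arsenal:
        route = _fresh("novel-route", member_routes_all)
    elif t.new_route.for_molecule:
        candidates = sorted(member_routes_all - sharing_routes)
        if not candidates:
            unsat("no route exists that is used in the arsenal but not for the molecule")
        route = rng.choice(candidates)
    else:
        if not sharing_routes:
            unsat("no member shares a substance, so any route is new for the molecule")
        route = rng.choice(sorted(sharing_routes))
    routes = {route}

    route_sharing = [
        m for m in members if routes & {normalize_term(r) for r in m.routes}
    ]
    sharing_forms = {normalize_term(m.pharmaceutical_form) for m in sharing}
    route_forms = {normalize_term(m.pharmaceutical_form) for m in route_sharing}

    # --- form --------------------------------------------------------------
    if t.new_form.for_arsenal:
        form = _fresh("novel-form", member_forms_all)
    else:
        candidates = [
            f
            for f in sorted(member_forms_all)
            if (f not in sharing_forms) == t.new_form.for_molecule
            and (f not in route_forms) == t.new_form.for_route
        ]
        if not candidates:
            unsat("no marketed form matches the requested form-novelty scopes")
        form = rng.choice(candidates)

    # --- presentation ------------------------------------------------------
    sharing_presentations = {
        normalize_term(m.presentation_term) for m in sharing
    } - {""}
    if t.new_presentation:
        presentation = _fresh("novel-presentation", sharing_presentations)
    elif sharing_presentations:
        presentation = rng.choice(sorted(sharing_presentations))
    else:
        presentation = ""  # no stated presentation: never counted as novel

    # --- dosing ------------------------------------------------------------
    member_values = [
        m.dosing.dose_per_intake_value
        for m in members
        if m.dosing.dose_per_intake_value is not None
    ]
    member_intakes = [
        m.dosing.intakes_per_day for m in members if m.dosing.intakes_per_day is not None
    ]
    sharing_triples = {m.dosing.protocol_triple() for m in sharing}
    if t.new_dose:
        dosing = Dosing(
            dose_per_intake_value=max(member_values, default=0.0) + 1.0,
            dose_per_intake_unit="mg",
            intakes_per_day=1.0,
            units_per_intake=1,
        )
    elif t.new_protocol:
        donors = [m for m in sharing if m.dosing.dose() != (None, None)]
        fresh_intakes = max(member_intakes, default=0.0) + 1.0
        if donors:
            donor = rng.choice(donors)
            dosing = Dosing(
                dose_per_intake_value=donor.dosing.dose_per_intake_value,
                dose_per_intake_unit=donor.dosing.dose_per_intake_unit,
                intakes_per_day=fresh_intakes,
                units_per_intake=donor.dosing.units_per_intake,
            )
        else:
            dosing = Dosing(intakes_per_day=fresh_intakes)
        if dosing.protocol_triple() in sharing_triples:
            unsat("cannot vary the protocol without varying the dose")
    else:
        donors = [m for m in sharing]
        if donors:
            donor = rng.choice(donors)
            dosing = replace(donor.dosing)
        else:
            dosing = Dosing()  # fully unknown regimen: nothing to be novel in

    # --- pharmacology ------------------------------------------------------
    member_mechanisms = {normalize_term(m.mechanism_term) for m in members}
    member_groups = {normalize_term(m.pharmacotherapeutic_group) for m in members}
    if t.new_mechanism_of_action:
        mechanism = _fresh("novel-mechanism", member_mechanisms)
    else:
        if not member_mechanisms:
            unsat("every mechanism is new against an empty arsenal")
        mechanism = rng.choice(sorted(member_mechanisms))
    if t.new_pharmacotherapeutic_group:
        group = _fresh("novel-group", member_groups)
    else:
        if not member_groups:
            unsat("every group is new against an empty arsenal")
        group = rng.choice(sorted(member_groups))

    # --- record ------------------------------------------------------------
    record = ProductRecord(
        brand_name=f"candidate-{seed}",
        substances=substances,
        pharmaceutical_form=form,
        routes=routes,
        presentation_term=presentation,
        pharmacotherapeutic_group=group,
        mechanism_term=mechanism,
        indications=[replace(arsenal.indication)],
        dosing=dosing,
        overdose=Overdose(risk_grade="moderate", antidote_available="no"),
        invasiveness_grade="noninvasive",
    )
    prior_labels = (
        [] if t.new_indication_or_extension else [replace(arsenal.indication)]
    )
    problems = validate_product(record)
    if problems:  # pragma: no cover - constructive steps keep records valid
        unsat(f"constructed record is invalid: {problems[0]}")
    achieved = summarize_novelty(record, arsenal, prior_labels)
    if achieved != t:
        unsat(
            "target profile is not realisable over this arsenal "
            f"(closest construction classifies as {achieved})"
        )
    return record, prior_labels


# ---------------------------------------------------------------------------
# Encoded study fixtures


@dataclass(frozen=True)
class CaseTriple:
    """One classification case: a product, its arsenal and the product
    line's previously approved labels."""

    product: ProductRecord
    arsenal: TherapeuticArsenal
    prior_labels: tuple = ()


def _std_dosing(value: float, intakes: float = 2.0) -> Dosing:
    return Dosing(
        dose_per_intake_value=value,
        dose_per_intake_unit="mg",
        intakes_per_day=intakes,
        units_per_intake=1,
    )


def _base_member(
    brand: str,
    inn: str,
    indication: Indication,
    route: str,
    form: str,
    presentation: str,
    mechanism: str,
    group: str,
    dose: float,
    intakes: float = 2.0,
    substances: list[Substance] | None = None,
) -> ProductRecord:
    return ProductRecord(
        brand_name=brand,
        substances=substances
        or [Substance(inn_name=inn, strength_value=dose, strength_unit="mg")],
        pharmaceutical_form=form,
        routes={route},
        presentation_term=presentation,
        pharmacotherapeutic_group=group,
        mechanism_term=mechanism,
        indications=[replace(indication)],
        dosing=_std_dosing(dose, intakes),
        serious_adr_terms={"nausea"},
        contraindication_terms={"hypersensitivity to the active substance"},
        overdose=Overdose(risk_grade="moderate", antidote_available="no"),
        invasiveness_grade="noninvasive",
        convenience_grade="medium",
        dose_adjustability_grade="moderate",
    )


def _sample_arsenal(i: int, with_combination: bool) -> TherapeuticArsenal:
    """Tailored three/four-member arsenal for synthetic sample case ``i``."""
    ind = Indication(
        condition_term=f"condition-{i:02d}",
        target_kind="disease",
        treatment_type="curative",
    )
    alpha, beta, gamma = f"alpha-{i:02d}", f"beta-{i:02d}", f"gamma-{i:02d}"
    mech, group = f"mechanism-{i:02d}", f"group-{i:02d}"
    a = _base_member(
        f"brand-a-{i:02d}", alpha, ind, "oral", "tablet", "blister pack",
        mech, group, 10.0,
    )
    b = _base_member(
        f"brand-b-{i:02d}", beta, ind, "intravenous", "solution for injection",
        "vial", mech, group, 5.0, intakes=1.0,
    )
    c = _base_member(
        f"brand-c-{i:02d}", gamma, ind, "intravenous", "tablet", "blister pack",
        mech, group, 10.0,
    )
    members = [a, b, c]
    if with_combination:
        members.append(
            _base_member(
                f"brand-d-{i:02d}", alpha, ind, "oral", "tablet", "blister pack",
                mech, group, 10.0,
                substances=[
                    Substance(inn_name=alpha, strength_value=10.0, strength_unit="mg"),
                    Substance(inn_name=beta, strength_value=5.0, strength_unit="mg"),
                ],
            )
        )
    return TherapeuticArsenal(
        indication=ind,
        members=members,
        known_molecule_registry={alpha, beta, gamma},
    )


def _twin_of(member: ProductRecord, brand: str) -> ProductRecord:
    twin = replace(
        member,
        brand_name=brand,
        substances=[replace(s) for s in member.substances],
        routes=set(member.routes),
        indications=[replace(i) for i in member.indications],
        dosing=replace(member.dosing),
        overdose=replace(member.overdose),
        serious_adr_terms=set(member.serious_adr_terms),
        contraindication_terms=set(member.contraindication_terms),
        serious_ddi_terms=set(member.serious_ddi_terms),
        monitoring_test_terms=set(member.monitoring_test_terms),
    )
    return twin


def design_sample_fixture() -> list[CaseTriple]:
    """The 40-record design sample, as raw attributes.

    The records are engineered so that classification reproduces the
    sample's printed aggregate composition — 11 new molecules (8 with a new
    mechanism of action and a new pharmacotherapeutic group), 5 new
    combinations, and 24 known molecules of which 10 carry new usage
    features and 14 a new indication or extension — without ever assigning a
    category label directly.  Fully deterministic: rebuilding gives
    byte-identical documents.
    """
    cases: list[CaseTriple] = []
    i = 0

    def next_arsenal() -> TherapeuticArsenal:
        nonlocal i
        arsenal = _sample_arsenal(i, with_combination=False)
        i += 1
        return arsenal

    # 8 new molecules with new mechanism + new group, 3 without.
    for new_mech in [True] * 8 + [False] * 3:
        ars = next_arsenal()
        a = ars.members[0]
        product = _twin_of(a, f"design-newmol-{i:02d}")
        product.substances = [
            Substance(inn_name=f"nova-{i:02d}", strength_value=10.0, strength_unit="mg")
        ]
        if new_mech:
            product.mechanism_term = f"novel-mechanism-{i:02d}"
            product.pharmacotherapeutic_group = f"novel-group-{i:02d}"
        cases.append(CaseTriple(product, ars, (replace(ars.indication),)))

    # 5 new combinations of two marketed molecules.
    for _ in range(5):
        ars = next_arsenal()
        a, b = ars.members[0], ars.members[1]
        product = _twin_of(a, f"design-combo-{i:02d}")
        product.substances = [
            replace(a.substances[0]),
            replace(b.substances[0]),
        ]
        cases.append(CaseTriple(product, ars, (replace(ars.indication),)))

    # 14 known molecules with a new indication or extension (attribute twins
    # of a marketed member; no previously approved label).
    for _ in range(14):
        ars = next_arsenal()
        product = _twin_of(ars.members[0], f"design-newind-{i:02d}")
        cases.append(CaseTriple(product, ars, ()))

    # 10 known molecules with one new usage feature each.
    features = ["form"] * 3 + ["route"] * 3 + ["presentation"] * 2 + ["dose"] * 2
    for feature in features:
        ars = next_arsenal()
        a, b = ars.members[0], ars.members[1]
        product = _twin_of(a, f"design-feature-{i:02d}")
        if feature == "form":
            product.pharmaceutical_form = b.pharmaceutical_form
        elif feature == "route":
            product.routes = set(b.routes)
        elif feature == "presentation":
            product.presentation_term = "prefilled pen"
        elif feature == "dose":
            product.dosing = _std_dosing(20.0)
        cases.append(CaseTriple(product, ars, (replace(ars.indication),)))

    assert len(cases) == 40
    return cases


def completeness_fixture() -> list[CaseTriple]:
    """The 20-record completeness-analysis sample, as raw attributes.

    Reproduces the printed composition — 6 new molecules (5 with new
    mechanism and group), 3 new combinations, 2 marketed combinations with a
    new dosage, and 9 known molecules (3 with new features, 6 with a new
    indication, 2 of those with a new mechanism and group for the new
    indication).  Exactly one record states a duration of administration,
    the single attribute the v1 model has no slot for.
    """
    cases: list[CaseTriple] = []
    i = 100

    def next_arsenal() -> TherapeuticArsenal:
        nonlocal i
        arsenal = _sample_arsenal(i, with_combination=True)
        i += 1
        return arsenal

    # 5 new molecules with new mechanism + group, 1 without.
    for new_mech in [True] * 5 + [False]:
        ars = next_arsenal()
        product = _twin_of(ars.members[0], f"compl-newmol-{i:02d}")
        product.substances = [
            Substance(inn_name=f"nova-{i:02d}", strength_value=10.0, strength_unit="mg")
        ]
        if new_mech:
            product.mechanism_term = f"novel-mechanism-{i:02d}"
            product.pharmacotherapeutic_group = f"novel-group-{i:02d}"
        cases.append(CaseTriple(product, ars, (replace(ars.indication),)))

    # 3 new combinations (alpha + gamma; only alpha + beta is marketed).
    for _ in range(3):
        ars = next_arsenal()
        a, c = ars.members[0], ars.members[2]
        product = _twin_of(a, f"compl-combo-{i:02d}")
        product.substances = [replace(a.substances[0]), replace(c.substances[0])]
        cases.append(CaseTriple(product, ars, (replace(ars.indication),)))

    # 2 marketed combinations with a new dosage; the second also states a
    # duration of administration (the v1 coverage gap).
    for k in range(2):
        ars = next_arsenal()
        d = ars.members[3]
        product = _twin_of(d, f"compl-combodose-{i:02d}")
        product.dosing = _std_dosing(25.0)
        if k == 1:
            product.dosing.duration_days = 7.0
        cases.append(CaseTriple(product, ars, (replace(ars.indication),)))

    # 3 known molecules with one new usage feature each.
    for feature in ("form", "route", "presentation"):
        ars = next_arsenal()
        a, b = ars.members[0], ars.members[1]
        product = _twin_of(a, f"compl-feature-{i:02d}")
        if feature == "form":
            product.pharmaceutical_form = b.pharmaceutical_form
        elif feature == "route":
            product.routes = set(b.routes)
        else:
            product.presentation_term = "prefilled pen"
        cases.append(CaseTriple(product, ars, (replace(ars.indication),)))

    # 6 known molecules with a new indication; 2 of them with a new
    # mechanism and group for that indication.
    for new_mech in [True] * 2 + [False] * 4:
        ars = next_arsenal()
        product = _twin_of(ars.members[0], f"compl-newind-{i:02d}")
        if new_mech:
            product.mechanism_term = f"novel-mechanism-{i:02d}"
            product.pharmacotherapeutic_group = f"novel-group-{i:02d}"
        cases.append(CaseTriple(product, ars, ()))

    assert len(cases) == 20
    return cases


# ---------------------------------------------------------------------------
# Worked examples


@dataclass(frozen=True)
class EfientFixture:
    new: ProductRecord
    comparator: ProductRecord
    arsenal: TherapeuticArsenal
    prior_labels: tuple
    evidence: tuple


def efient_fixture() -> EfientFixture:
    """The antiplatelet worked example: Efient (prasugrel hydrochloride
    10 mg, film-coated tablets), co-administered with acetylsalicylic acid
    for the prevention of atherothrombotic events, assessed against Plavix
    (clopidogrel 75 mg, tablets).

    Safety term sets are illustrative designed content with the right shape
    (shared, new-only and comparator-only terms), not transcribed SPC data.
    """
    indication = Indication(
        condition_term="prevention of atherothrombotic events",
        target_kind="risk_factor",
        treatment_type="preventive",
        coadministration_terms={"acetylsalicylic acid"},
    )
    plavix = ProductRecord(
        brand_name="Plavix",
        substances=[
            Substance(
                inn_name="clopidogrel",
                atc_code="b01ac04",
                strength_value=75.0,
                strength_unit="mg",
            )
        ],
        pharmaceutical_form="tablet",
        routes={"oral"},
        presentation_term="blister pack",
        pharmacotherapeutic_group="platelet aggregation inhibitors",
        mechanism_term="irreversible p2y12 adp receptor antagonist",
        indications=[replace(indication)],
        dosing=Dosing(
            dose_per_intake_value=75.0,
            dose_per_intake_unit="mg",
            intakes_per_day=1.0,
            units_per_intake=1,
        ),
        serious_adr_terms={
            "haemorrhage",
            "anaemia",
            "thrombotic thrombocytopenic purpura",
        },
        contraindication_terms={
            "active pathological bleeding",
            "severe hepatic impairment",
        },
        serious_ddi_terms={"omeprazole"},
        overdose=Overdose(risk_grade="moderate", antidote_available="no"),
        invasiveness_grade="noninvasive",
        convenience_grade="medium",
        dose_adjustability_grade="moderate",
    )
    efient = ProductRecord(
        brand_name="Efient",
        substances=[
            Substance(
                inn_name="prasugrel",
                atc_code="b01ac22",
                strength_value=10.0,
                strength_unit="mg",
            )
        ],
        pharmaceutical_form="film-coated tablet",
        routes={"oral"},
        presentation_term="blister pack",
        pharmacotherapeutic_group="platelet aggregation inhibitors",
        mechanism_term="irreversible p2y12 adp receptor antagonist",
        indications=[replace(indication)],
        dosing=Dosing(
            dose_per_intake_value=10.0,
            dose_per_intake_unit="mg",
            intakes_per_day=1.0,
            units_per_intake=1,
        ),
        serious_adr_terms={
            "haemorrhage",
            "anaemia",
            "hypersensitivity including angioedema",
        },
        contraindication_terms={
            "active pathological bleeding",
            "history of stroke or transient ischaemic attack",
            "severe hepatic impairment",
        },
        serious_ddi_terms=set(),
        overdose=Overdose(risk_grade="moderate", antidote_available="no"),
        invasiveness_grade="noninvasive",
        convenience_grade="medium",
        dose_adjustability_grade="moderate",
    )
    arsenal = TherapeuticArsenal(
        indication=indication,
        members=[plavix],
        known_molecule_registry={
            "clopidogrel",
            "acetylsalicylic acid",
            "ticlopidine",
        },
    )
    evidence = (
        EfficacyEvidence(
            endpoint_category="prevention.complications",
            direction="superior",
            source_note="fewer ischaemic events than with the comparator",
        ),
    )
    return EfientFixture(
        new=efient,
        comparator=plavix,
        arsenal=arsenal,
        prior_labels=(),
        evidence=evidence,
    )


@dataclass(frozen=True)
class EpipenFixture:
    product: ProductRecord
    arsenal: TherapeuticArsenal
    prior_labels: tuple


def epipen_fixture() -> EpipenFixture:
    """The new-presentation worked example: an epinephrine auto-injector
    (single dose of 0.15 mg epinephrine injection/0.3 ml) whose novelty lies
    in the model of injector, against an arsenal of epinephrine ampoules."""
    indication = Indication(
        condition_term="emergency treatment of anaphylaxis",
        target_kind="symptom",
        treatment_type="symptomatic",
    )
    ampoule = ProductRecord(
        brand_name="Epinephrine ampoules",
        substances=[
            Substance(
                inn_name="epinephrine", strength_value=0.15, strength_unit="mg"
            )
        ],
        pharmaceutical_form="solution for injection",
        routes={"intramuscular"},
        presentation_term="glass ampoule",
        pharmacotherapeutic_group="adrenergic agents",
        mechanism_term="alpha and beta adrenergic receptor agonist",
        indications=[replace(indication)],
        dosing=Dosing(
            dose_per_intake_value=0.15,
            dose_per_intake_unit="mg",
            intakes_per_day=1.0,
            units_per_intake=1,
        ),
        serious_adr_terms={"ventricular arrhythmia"},
        overdose=Overdose(risk_grade="high", antidote_available="no"),
        invasiveness_grade="minimally_invasive",
    )
    epipen = _twin_of(ampoule, "Epipen")
    epipen.presentation_term = "auto-injector"
    arsenal = TherapeuticArsenal(
        indication=indication,
        members=[ampoule],
        known_molecule_registry={"epinephrine"},
    )
    return EpipenFixture(
        product=epipen, arsenal=arsenal, prior_labels=(replace(indication),)
    )
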