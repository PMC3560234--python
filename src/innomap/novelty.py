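"""Novelty classification of a new manufactured product against its
therapeutic arsenal.

A product's *nature of novelty* is described by one mutually exclusive
top-level category plus a set of aspect flags:

* top level — ``new_molecule`` (≥1 substance absent from the known-molecule
  registry), else ``new_combination`` (a multi-substance composition matching
  no marketed member), else ``known_molecule``.  Precedence
  new_molecule > new_combination > known_molecule makes the categories a
  partition, so tallies over a drug sample sum to the sample size.
* pharmacology — new mechanism of action / new pharmacotherapeutic group,
  each assessed against the union of that attribute over arsenal members.
* usage — new route, form, dose, presentation or protocol.  Route and form
  carry scopes: novel *for the molecule* (against members sharing ≥1
  substance), *for the route* (form only; against members sharing a route) or
  *for the whole arsenal*.  Dose, presentation and protocol are
  molecule-scoped.
* regulatory — a new indication or an extension of the previous indication,
  assessed against the product line's previously approved labels.

Every flag is an "absent from a membership union" test, so enlarging the
arsenal can only turn flags off, never on (novelty shrinks as the market
grows), and an empty comparison set yields vacuous novelty (a new molecule is
trivially novel in every molecule-scoped aspect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

from .model import (
    ContractError,
    Indication,
    ProductRecord,
    TherapeuticArsenal,
    in_registry,
    normalize_term,
    validate_product,
)

__all__ = [
    "FormNovelty",
    "NoveltyProfile",
    "RouteNovelty",
    "TOP_LEVELS",
    "UsageNovelty",
    "classify_top_level",
    "detect_indication_novelty",
    "detect_mechanism_novelty",
    "detect_usage_novelty",
    "profile_from_document",
    "profile_to_document",
    "summarize_novelty",
    "tally_novelty",
]

TOP_LEVELS = ("new_molecule", "new_combination", "known_molecule")


@dataclass(frozen=True)
class RouteNovelty:
    for_molecule: bool = False
    for_arsenal: bool = False


@dataclass(frozen=True)
class FormNovelty:
    for_molecule: bool = False
    for_route: bool = False
    for_arsenal: bool = False


@dataclass(frozen=True)
class UsageNovelty:
    new_route: RouteNovelty = RouteNovelty()
    new_form: FormNovelty = FormNovelty()
    new_dose: bool = False
    new_presentation: bool = False
    new_protocol: bool = False


@dataclass(frozen=True)
class NoveltyProfile:
    """The derived novelty flag set; exactly one top-level category."""

    top_level: str
    new_mechanism_of_action: bool = False
    new_pharmacotherapeutic_group: bool = False
    known_combination_new_form: bool = False
    new_route: RouteNovelty = RouteNovelty()
    new_form: FormNovelty = FormNovelty()
    new_dose: bool = False
    new_presentation: bool = False
    new_protocol: bool = False
    new_indication_or_extension: bool = False

    def __post_init__(self):
        if self.top_level not in TOP_LEVELS:
            raise ValueError(f"top_level must be one of {TOP_LEVELS}")
        if self.known_combination_new_form and self.top_level == "new_molecule":
            raise ValueError(
                "known_combination_new_form requires a non-new-molecule top level"
            )

    def flags(self) -> dict[str, bool]:
        """Flat flag dictionary (top level excluded)."""
        return {
            "new_mechanism_of_action": self.new_mechanism_of_action,
            "new_pharmacotherapeutic_group": self.new_pharmacotherapeutic_group,
            "known_combination_new_form": self.known_combination_new_form,
            "new_route.for_molecule": self.new_route.for_molecule,
            "new_route.for_arsenal": self.new_route.for_arsenal,
            "new_form.for_molecule": self.new_form.for_molecule,
            "new_form.for_route": self.new_form.for_route,
            "new_form.for_arsenal": self.new_form.for_arsenal,
            "new_dose": self.new_dose,
            "new_presentation": self.new_presentation,
            "new_protocol": self.new_protocol,
            "new_indication_or_extension": self.new_indication_or_extension,
        }

    @property
    def has_usage_novelty(self) -> bool:
        """True when the product brings any new usage feature (new form,
        route, presentation, dose or protocol)."""
        return (
            self.new_route.for_molecule
            or self.new_route.for_arsenal
            or self.new_form.for_molecule
            or self.new_form.for_route
            or self.new_form.for_arsenal
            or self.new_dose
            or self.new_presentation
            or self.new_protocol
        )


def _require_valid(product: ProductRecord) -> None:
    violations = validate_product(product)
    if violations:
        raise ContractError(
            f"product {product.brand_name!r} is not valid: {violations[0]}"
        )


def classify_top_level(product: ProductRecord, arsenal: TherapeuticArsenal) -> str:
    """Assign the mutually exclusive top-level novelty category."""
    _require_valid(product)
    registry = arsenal.known_molecule_registry
    if any(not in_registry(s, registry) for s in product.substances):
        return "new_molecule"
    if product.is_combination and not any(
        product.same_composition(m) for m in arsenal.members
    ):
        return "new_combination"
    return "known_molecule"


def detect_mechanism_novelty(
    product: ProductRecord, arsenal: TherapeuticArsenal
) -> tuple[bool, bool]:
    """(new mechanism of action, new pharmacotherapeutic group) versus the
    unions of those attributes over arsenal members.  Independent flags: the
    two may co-occur but neither implies the other."""
    mechanisms = {normalize_term(m.mechanism_term) for m in arsenal.members}
    groups = {normalize_term(m.pharmacotherapeutic_group) for m in arsenal.members}
    return (
        normalize_term(product.mechanism_term) not in mechanisms,
        normalize_term(product.pharmacotherapeutic_group) not in groups,
    )


def detect_usage_novelty(
    product: ProductRecord, arsenal: TherapeuticArsenal
) -> UsageNovelty:
    """Route/form/dose/presentation/protocol novelty with scopes.

    The molecule-scoped comparison set is the arsenal members sharing at
    least one substance with the product; the route-scoped set (form only)
    is the members sharing at least one route.
    """
    _require_valid(product)
    members = arsenal.members
    sharing = [m for m in members if product.shares_substance(m)]
    routes = {normalize_term(r) for r in product.routes}

    def member_routes(ms):
        return {normalize_term(r) for m in ms for r in m.routes}

    route_sharing = [
        m for m in members if routes & {normalize_term(r) for r in m.routes}
    ]

    new_route = RouteNovelty(
        for_molecule=not (routes & member_routes(sharing)),
        for_arsenal=not (routes & member_routes(members)),
    )

    form = normalize_term(product.pharmaceutical_form)

    def member_forms(ms):
        return {normalize_term(m.pharmaceutical_form) for m in ms}

    new_form = FormNovelty(
        for_molecule=form not in member_forms(sharing),
        for_route=form not in member_forms(route_sharing),
        for_arsenal=form not in member_forms(members),
    )

    dose = product.dosing.dose()
    new_dose = dose != (None, None) and dose not in {
        m.dosing.dose() for m in sharing
    }

    presentation = normalize_term(product.presentation_term)
    new_presentation = bool(presentation) and presentation not in {
        normalize_term(m.presentation_term) for m in sharing
    }

    triple = product.dosing.protocol_triple()
    new_protocol = any(x is not None for x in triple) and triple not in {
        m.dosing.protocol_triple() for m in sharing
    }

    return UsageNovelty(
        new_route=new_route,
        new_form=new_form,
        new_dose=new_dose,
        new_presentation=new_presentation,
        new_protocol=new_protocol,
    )


def detect_indication_novelty(
    product: ProductRecord, prior_labels: list[Indication]
) -> bool:
    """True iff the product claims a condition absent from the product
    line's previously approved labels (a new indication, or an extension of
    the previous indication)."""
    prior = {normalize_term(i.condition_term) for i in prior_labels}
    return any(term not in prior for term in product.indication_terms())


def summarize_novelty(
    product: ProductRecord,
    arsenal: TherapeuticArsenal,
    prior_labels: list[Indication] = (),
) -> NoveltyProfile:
    """Compose the detectors into a full :class:`NoveltyProfile`.

    ``known_combination_new_form`` is derived, not detected separately: a
    marketed combination (top level ``known_molecule``, ≥2 substances)
    reappearing in a form novel for its molecules.
    """
    _require_valid(product)
    top = classify_top_level(product, arsenal)
    new_mech, new_group = detect_mechanism_novelty(product, arsenal)
    usage = detect_usage_novelty(product, arsenal)
    return NoveltyProfile(
        top_level=top,
        new_mechanism_of_action=new_mech,
        new_pharmacotherapeutic_group=new_group,
        known_combination_new_form=(
            top == "known_molecule"
            and product.is_combination
            and usage.new_form.for_molecule
        ),
        new_route=usage.new_route,
        new_form=usage.new_form,
        new_dose=usage.new_dose,
        new_presentation=usage.new_presentation,
        new_protocol=usage.new_protocol,
        new_indication_or_extension=detect_indication_novelty(
            product, list(prior_labels)
        ),
    )


def tally_novelty(profiles) -> dict:
    """Counts per top-level category and per flag over a profile collection.

    Category counts partition the input; each flag count is at most the
    input size.
    """
    profiles = list(profiles)
    top = Counter(p.top_level for p in profiles)
    flags: Counter = Counter()
    for p in profiles:
        for name, value in p.flags().items():
            if value:
                flags[name] += 1
    return {
        "n": len(profiles),
        "top_level": {cat: top.get(cat, 0) for cat in TOP_LEVELS},
        "flags": dict(sorted(flags.items())),
    }


# ---------------------------------------------------------------------------
# Document form


def profile_to_document(profile: NoveltyProfile) -> dict:
    return {
        "top_level": profile.top_level,
        "new_mechanism_of_action": profile.new_mechanism_of_action,
        "new_pharmacotherapeutic_group": profile.new_pharmacotherapeutic_group,
        "known_combination_new_form": profile.known_combination_new_form,
        "new_route": {
            "for_molecule": profile.new_route.for_molecule,
            "for_arsenal": profile.new_route.for_arsenal,
        },
        "new_form": {
            "for_molecule": profile.new_form.for_molecule,
            "for_route": profile.new_form.for_route,
            "for_arsenal": profile.new_form.for_arsenal,
        },
        "new_dose": profile.new_dose,
        "new_presentation": profile.new_presentation,
        "new_protocol": profile.new_protocol,
        "new_indication_or_extension": profile.new_indication_or_extension,
    }


def profile_from_document(document: dict) -> NoveltyProfile:
    route = document.get("new_route", {})
    form = document.get("new_form", {})
    return NoveltyProfile(
        top_level=document["top_level"],
        new_mechanism_of_action=document.get("new_mechanism_of_action", False),
        new_pharmacotherapeutic_group=document.get(
            "new_pharmacotherapeutic_group", False
        ),
        known_combination_new_form=document.get("known_combination_new_form", False),
        new_route=RouteNovelty(
            for_molecule=route.get("for_molecule", False),
            for_arsenal=route.get("for_arsenal", False),
        ),
        new_form=FormNovelty(
            for_molecule=form.get("for_molecule", False),
            for_route=form.get("for_route", False),
            for_arsenal=form.get("for_arsenal", False),
        ),
        new_dose=document.get("new_dose", False),
        new_presentation=document.get("new_presentation", False),
        new_protocol=document.get("new_protocol", False),
        new_indication_or_extension=document.get(
            "new_indication_or_extension", False
        ),
    )
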