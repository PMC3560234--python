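"""Item-level impact of a new product versus one comparator.

Impact is assessed along three dimensions — efficacy, safety and ease of use
— and every item receives one verdict: ``positive`` (favours the new
product), ``equivalent``, ``negative`` (favours the comparator) or
``not_assessable`` (one side unknown, or no comparative evidence).

Safety term sets (serious adverse reactions, contraindications, serious
drug-drug interactions) are compared by presence/absence: a term listed only
for the new product is a *negative* impact (an extra harm), a term listed
only for the comparator is *positive* (a harm avoided), a term in both is
*equivalent*.  The overdose item combines the ordinal risk grade
(low < moderate < high, lower is better) with antidote availability (yes
beats no); a conflict between the two components is not assessable.

Efficacy is an input assertion — a trial direction (superior / non_inferior
/ inferior / not_assessable) on one endpoint category — not something
computed from trial data; absent comparative trials the caller supplies
``not_assessable`` (expert-conclusion territory).

Ease of use covers the patient side (units per intake, intakes per day,
duration of administration, invasiveness, convenience) and the physician
side (monitoring burden, dose adjustability).

All comparisons are antisymmetric: swapping the two products maps positive
verdicts to negative and vice versa; equivalent and not_assessable are fixed
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import ContractError, ProductRecord, normalize_term, validate_product

__all__ = [
    "DIMENSIONS",
    "EfficacyEvidence",
    "ImpactItem",
    "ImpactProfile",
    "VERDICTS",
    "aggregate_impact",
    "compare_ease_of_use",
    "compare_efficacy",
    "compare_item_sets",
    "compare_safety",
    "impact_profile_from_document",
    "impact_profile_to_document",
]

DIMENSIONS = ("efficacy", "safety", "ease_of_use")
VERDICTS = ("positive", "equivalent", "negative", "not_assessable")

ENDPOINT_CATEGORIES = (
    "course_of_disease.cure",
    "course_of_disease.stabilization",
    "course_of_disease.remission",
    "symptomatology",
    "measurable_parameter",
    "prevention.disease_occurrence",
    "prevention.complications",
)
DIRECTIONS = ("superior", "non_inferior", "inferior", "not_assessable")

_RISK_ORDER = {"low": 0, "moderate": 1, "high": 2}
_ANTIDOTE_ORDER = {"no": 0, "yes": 1}
_INVASIVENESS_ORDER = {"noninvasive": 0, "minimally_invasive": 1, "invasive": 2}
_CONVENIENCE_ORDER = {"low": 0, "medium": 1, "high": 2}
_ADJUSTABILITY_ORDER = {"difficult": 0, "moderate": 1, "easy": 2}


@dataclass(frozen=True)
class EfficacyEvidence:
    """One comparative-efficacy assertion: endpoint category + direction."""

    endpoint_category: str
    direction: str
    source_note: str = ""

    def __post_init__(self):
        if self.endpoint_category not in ENDPOINT_CATEGORIES:
            raise ValueError(
                f"endpoint_category must be one of {ENDPOINT_CATEGORIES}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    def flipped(self) -> "EfficacyEvidence":
        """The same evidence read from the comparator's viewpoint."""
        swap = {"superior": "inferior", "inferior": "superior"}
        return replace(self, direction=swap.get(self.direction, self.direction))


@dataclass(frozen=True)
class ImpactItem:
    dimension: str  # efficacy | safety | ease_of_use
    subcategory: str  # e.g. serious_adr, overdose, intakes_per_day, monitoring
    item_term: str
    verdict: str
    rationale: str = ""

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"dimension must be one of {DIMENSIONS}")
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be one of {VERDICTS}")
        if self.verdict != "equivalent" and not self.rationale:
            raise ValueError("non-equivalent verdicts require a rationale")


@dataclass
class ImpactProfile:
    comparator_ref: str
    items: list[ImpactItem] = field(default_factory=list)
    dimension_summaries: dict[str, str] = field(default_factory=dict)


def _require_valid(record: ProductRecord) -> None:
    violations = validate_product(record)
    if violations:
        raise ContractError(
            f"record {record.brand_name!r} is not valid: {violations[0]}"
        )


def compare_item_sets(
    new_terms: set, comparator_terms: set, subcategory: str,
    dimension: str = "safety",
) -> list[ImpactItem]:
    """Presence/absence comparison of two normalized term sets.

    One item per term in the union, under the harm-direction convention:
    only in the new product → negative, only in the comparator → positive,
    in both → equivalent.  Terms in neither set are never emitted.
    """
    items = []
    for term in sorted(new_terms | comparator_terms):
        in_new, in_cmp = term in new_terms, term in comparator_terms
        if in_new and in_cmp:
            verdict, why = "equivalent", "listed for both products"
        elif in_new:
            verdict, why = "negative", "listed only for the new product"
        else:
            verdict, why = "positive", "listed only for the comparator"
        items.append(
            ImpactItem(
                dimension=dimension,
                subcategory=subcategory,
                item_term=term,
                verdict=verdict,
                rationale=why,
            )
        )
    return items


def _ordinal_verdict(new_rank, cmp_rank, higher_is_better: bool):
    # Equality first: an attribute unknown on *both* sides is equally
    # unspecified, hence equivalent; one-sided unknowns are not assessable.
    if new_rank == cmp_rank:
        return "equivalent"
    if new_rank is None or cmp_rank is None:
        return "not_assessable"
    better = (new_rank > cmp_rank) == higher_is_better
    return "positive" if better else "negative"


def _overdose_item(new: ProductRecord, comparator: ProductRecord) -> ImpactItem:
    nr = _RISK_ORDER.get(new.overdose.risk_grade)
    cr = _RISK_ORDER.get(comparator.overdose.risk_grade)
    na = _ANTIDOTE_ORDER.get(new.overdose.antidote_available)
    ca = _ANTIDOTE_ORDER.get(comparator.overdose.antidote_available)
    if (
        new.overdose.risk_grade == comparator.overdose.risk_grade
        and new.overdose.antidote_available == comparator.overdose.antidote_available
    ):
        return ImpactItem(
            dimension="safety",
            subcategory="overdose",
            item_term="overdose risk and antidote",
            verdict="equivalent",
            rationale="same risk grade and antidote availability",
        )
    if None in (nr, cr, na, ca):
        verdict, why = "not_assessable", "overdose risk or antidote unknown"
    else:
        risk_sign = (cr > nr) - (cr < nr)  # +1 when the new product risks less
        antidote_sign = (na > ca) - (na < ca)
        if risk_sign == 0 and antidote_sign == 0:
            verdict, why = "equivalent", "same risk grade and antidote availability"
        elif risk_sign * antidote_sign < 0:
            verdict, why = (
                "not_assessable",
                "risk grade and antidote availability point in opposite directions",
            )
        elif risk_sign + antidote_sign > 0:
            verdict, why = "positive", "lower overdose risk or antidote available"
        else:
            verdict, why = "negative", "higher overdose risk or antidote lacking"
    return ImpactItem(
        dimension="safety",
        subcategory="overdose",
        item_term="overdose risk and antidote",
        verdict=verdict,
        rationale=why,
    )


def compare_safety(new: ProductRecord, comparator: ProductRecord) -> list[ImpactItem]:
    """Safety items: the three SPC term-set comparisons plus the overdose
    item."""
    _require_valid(new)
    _require_valid(comparator)
    items: list[ImpactItem] = []
    for attr, sub in (
        ("serious_adr_terms", "serious_adr"),
        ("contraindication_terms", "contraindication"),
        ("serious_ddi_terms", "serious_ddi"),
    ):
        items.extend(
            compare_item_sets(
                {normalize_term(t) for t in getattr(new, attr)},
                {normalize_term(t) for t in getattr(comparator, attr)},
                sub,
            )
        )
    items.append(_overdose_item(new, comparator))
    return items


def compare_efficacy(evidence: EfficacyEvidence) -> ImpactItem:
    """Map an efficacy assertion to a verdict: superior → positive,
    non_inferior → equivalent, inferior → negative; not_assessable passes
    through."""
    mapping = {
        "superior": ("positive", "superiority shown"),
        "non_inferior": ("equivalent", ""),
        "inferior": ("negative", "inferiority shown"),
        "not_assessable": ("not_assessable", "no comparative evidence"),
    }
    verdict, why = mapping[evidence.direction]
    return ImpactItem(
        dimension="efficacy",
        subcategory=evidence.endpoint_category,
        item_term=evidence.source_note or evidence.endpoint_category,
        verdict=verdict,
        rationale=why or evidence.source_note,
    )


def _numeric_item(subcategory, new_value, cmp_value, lower_is_better=True):
    if new_value == cmp_value:  # includes both-unknown: equally unspecified
        verdict, why = "equivalent", "equal for both products"
    elif new_value is None or cmp_value is None:
        verdict, why = "not_assessable", "value unknown for one product"
    else:
        better = (new_value < cmp_value) == lower_is_better
        verdict = "positive" if better else "negative"
        why = f"{new_value:g} vs {cmp_value:g} for the comparator"
    return ImpactItem(
        dimension="ease_of_use",
        subcategory=subcategory,
        item_term=subcategory.replace("_", " "),
        verdict=verdict,
        rationale=why,
    )


def _graded_item(subcategory, order, new_grade, cmp_grade, higher_is_better):
    verdict = _ordinal_verdict(
        order.get(new_grade), order.get(cmp_grade), higher_is_better
    )
    why = {
        "equivalent": "same grade for both products",
        "not_assessable": "grade unknown for at least one product",
    }.get(verdict, f"{new_grade} vs {cmp_grade} for the comparator")
    return ImpactItem(
        dimension="ease_of_use",
        subcategory=subcategory,
        item_term=subcategory.replace("_", " "),
        verdict=verdict,
        rationale=why,
    )


def compare_ease_of_use(
    new: ProductRecord, comparator: ProductRecord
) -> list[ImpactItem]:
    """Patient-side and physician-side ease-of-use items.

    Patient: fewer units per intake, fewer intakes per day, shorter duration
    of administration and lower invasiveness are positive; convenience is a
    pre-graded ordinal input.  Physician: a smaller monitoring-test burden
    and easier dose adjustment are positive.  An attribute unknown on one
    side only makes the item not assessable.
    """
    _require_valid(new)
    _require_valid(comparator)
    nd, cd = new.dosing, comparator.dosing
    items = [
        _numeric_item("units_per_intake", nd.units_per_intake, cd.units_per_intake),
        _numeric_item("intakes_per_day", nd.intakes_per_day, cd.intakes_per_day),
        _numeric_item("duration_days", nd.duration_days, cd.duration_days),
        _graded_item(
            "invasiveness",
            _INVASIVENESS_ORDER,
            new.invasiveness_grade,
            comparator.invasiveness_grade,
            higher_is_better=False,
        ),
        _graded_item(
            "convenience",
            _CONVENIENCE_ORDER,
            new.convenience_grade,
            comparator.convenience_grade,
            higher_is_better=True,
        ),
        _numeric_item(
            "monitoring",
            len(new.monitoring_test_terms),
            len(comparator.monitoring_test_terms),
        ),
        _graded_item(
            "dose_adjustability",
            _ADJUSTABILITY_ORDER,
            new.dose_adjustability_grade,
            comparator.dose_adjustability_grade,
            higher_is_better=True,
        ),
    ]
    return items


def summarize_dimension(items: list[ImpactItem]) -> str:
    """``no_impact`` iff every item is equivalent (vacuously for an empty
    dimension); otherwise ``impact`` when any item is decided, else
    ``not_assessable``."""
    if all(i.verdict == "equivalent" for i in items):
        return "no_impact"
    if any(i.verdict in ("positive", "negative") for i in items):
        return "impact"
    return "not_assessable"


def aggregate_impact(
    new: ProductRecord,
    comparator: ProductRecord,
    evidence: list[EfficacyEvidence] = (),
) -> ImpactProfile:
    """Full three-dimension impact profile of ``new`` versus one
    comparator."""
    _require_valid(new)
    _require_valid(comparator)
    items = [compare_efficacy(e) for e in evidence]
    items.extend(compare_safety(new, comparator))
    items.extend(compare_ease_of_use(new, comparator))
    summaries = {
        dim: summarize_dimension([i for i in items if i.dimension == dim])
        for dim in DIMENSIONS
    }
    return ImpactProfile(
        comparator_ref=comparator.brand_name,
        items=items,
        dimension_summaries=summaries,
    )


# ---------------------------------------------------------------------------
# Document form


def impact_profile_to_document(profile: ImpactProfile) -> dict:
    return {
        "comparator_ref": profile.comparator_ref,
        "items": [
            {
                "dimension": i.dimension,
                "subcategory": i.subcategory,
                "item_term": i.item_term,
                "verdict": i.verdict,
                "rationale": i.rationale,
            }
            for i in profile.items
        ],
        "dimension_summaries": dict(profile.dimension_summaries),
    }


def impact_profile_from_document(document: dict) -> ImpactProfile:
    return ImpactProfile(
        comparator_ref=document["comparator_ref"],
        items=[
            ImpactItem(
                dimension=i["dimension"],
                subcategory=i["subcategory"],
                item_term=i["item_term"],
                verdict=i["verdict"],
                rationale=i.get("rationale", ""),
            )
            for i in document["items"]
        ],
        dimension_summaries=dict(document.get("dimension_summaries", {})),
    )
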