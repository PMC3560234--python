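"""Domain model for structured drug-product records.

The central object is the :class:`ProductRecord`, a machine-readable extract
of the Summary of Product Characteristics (SPC) of one manufactured product:
its composition (INN substances with strengths), pharmaceutical form, routes,
presentation, pharmacotherapeutic group and mechanism of action, indications,
dosing regimen, safety term sets (serious adverse reactions, contraindications,
serious drug-drug interactions, overdose risk) and ease-of-use attributes.

A :class:`TherapeuticArsenal` groups the products marketed for one indication
together with a registry of the molecules already known to the market; it is
the comparison frame for novelty classification.

Records are plain mutable dataclasses.  Construction never validates, so that
invalid in-memory records can exist and be reported on: :func:`validate_product`
returns the full list of invariant violations (empty list = valid).  Document
I/O (:func:`read_record` / :func:`write_record`) is schema-checked and raises
:class:`ParseError` — a failure mode deliberately distinct from validation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import yaml

from .schemas import ParseError, check_document, get_schema

__all__ = [
    "ContractError",
    "Dosing",
    "Indication",
    "Overdose",
    "ParseError",
    "ProductRecord",
    "Substance",
    "TherapeuticArsenal",
    "Violation",
    "arsenal_from_document",
    "arsenal_to_document",
    "canonical_json",
    "normalize_term",
    "read_record",
    "same_molecule",
    "validate_arsenal",
    "validate_product",
    "write_record",
]

TARGET_KINDS = ("disease", "symptom", "risk_factor")
TREATMENT_TYPES = ("curative", "symptomatic", "substitutive", "preventive")
RISK_GRADES = ("low", "moderate", "high", "unknown")
YES_NO_UNKNOWN = ("yes", "no", "unknown")
INVASIVENESS_GRADES = ("noninvasive", "minimally_invasive", "invasive", "unknown")
CONVENIENCE_GRADES = ("low", "medium", "high", "unknown")
ADJUSTABILITY_GRADES = ("easy", "moderate", "difficult", "unknown")

_WS = re.compile(r"\s+")


class ContractError(ValueError):
    """An operation was called with inputs violating its precondition."""


def normalize_term(raw: str) -> str:
    """Normalize a free-text term: trim, case-fold, collapse whitespace.

    Idempotent: ``normalize_term(normalize_term(x)) == normalize_term(x)``.
    Empty input maps to the empty string; callers reject emptiness where it
    is invalid.
    """
    return _WS.sub(" ", raw.strip()).casefold()


def _normset(terms) -> set[str]:
    return {normalize_term(t) for t in terms if normalize_term(t)}


@dataclass
class Substance:
    """One active substance: INN, optional ATC code and strength."""

    inn_name: str
    atc_code: str | None = None
    strength_value: float | None = None
    strength_unit: str | None = None

    def normalized(self) -> "Substance":
        return replace(
            self,
            inn_name=normalize_term(self.inn_name),
            atc_code=normalize_term(self.atc_code) if self.atc_code else None,
            strength_unit=normalize_term(self.strength_unit)
            if self.strength_unit
            else None,
        )


def same_molecule(a: Substance, b: Substance) -> bool:
    """Molecule identity: ATC code when both sides carry one, else exact
    normalized-INN equality.  No fuzzy matching — classification must be
    deterministic and auditable."""
    if a.atc_code and b.atc_code:
        return normalize_term(a.atc_code) == normalize_term(b.atc_code)
    return normalize_term(a.inn_name) == normalize_term(b.inn_name)


def in_registry(sub: Substance, registry: set[str]) -> bool:
    """Registry membership of a substance.  The registry holds normalized
    molecule identifiers (INNs, optionally ATC codes)."""
    if sub.atc_code and normalize_term(sub.atc_code) in registry:
        return True
    return normalize_term(sub.inn_name) in registry


@dataclass
class Indication:
    condition_term: str
    target_kind: str  # disease | symptom | risk_factor
    treatment_type: str  # curative | symptomatic | substitutive | preventive
    coadministration_terms: set[str] = field(default_factory=set)


@dataclass
class Dosing:
    """Dosing regimen.  Missing components are explicit ``None`` (unknown),
    never silently defaulted."""

    dose_per_intake_value: float | None = None
    dose_per_intake_unit: str | None = None
    intakes_per_day: float | None = None
    duration_days: float | None = None
    units_per_intake: int | None = None

    def protocol_triple(self):
        """The protocol compared as a unit: dose per intake, intakes per day
        and duration of administration."""
        return (
            self.dose_per_intake_value,
            self.dose_per_intake_unit,
            self.intakes_per_day,
            self.duration_days,
        )

    def dose(self):
        return (self.dose_per_intake_value, self.dose_per_intake_unit)


@dataclass
class Overdose:
    risk_grade: str = "unknown"  # low | moderate | high | unknown
    antidote_available: str = "unknown"  # yes | no | unknown


@dataclass
class ProductRecord:
    """Structured SPC extract of one manufactured product."""

    brand_name: str
    substances: list[Substance]
    pharmaceutical_form: str
    routes: set[str]
    presentation_term: str
    pharmacotherapeutic_group: str
    mechanism_term: str
    indications: list[Indication]
    dosing: Dosing = field(default_factory=Dosing)
    serious_adr_terms: set[str] = field(default_factory=set)
    contraindication_terms: set[str] = field(default_factory=set)
    serious_ddi_terms: set[str] = field(default_factory=set)
    overdose: Overdose = field(default_factory=Overdose)
    monitoring_test_terms: set[str] = field(default_factory=set)
    invasiveness_grade: str = "unknown"
    convenience_grade: str = "unknown"
    dose_adjustability_grade: str = "unknown"

    @property
    def is_combination(self) -> bool:
        return len(self.substances) > 1

    def indication_terms(self) -> set[str]:
        return {normalize_term(i.condition_term) for i in self.indications}

    def shares_substance(self, other: "ProductRecord") -> bool:
        return any(
            same_molecule(a, b) for a in self.substances for b in other.substances
        )

    def same_composition(self, other: "ProductRecord") -> bool:
        """Multiset equality of substances under molecule identity."""
        return _multiset_match(self.substances, other.substances)


def _multiset_match(xs: list[Substance], ys: list[Substance]) -> bool:
    if len(xs) != len(ys):
        return False
    remaining = list(ys)
    for x in xs:  # backtracking unnecessary at SPC sizes; greedy on identity keys
        for i, y in enumerate(remaining):
            if same_molecule(x, y):
                del remaining[i]
                break
        else:
            return False
    return True


@dataclass
class TherapeuticArsenal:
    """All products marketed for one indication, plus the registry of
    molecule identifiers already known to the market."""

    indication: Indication
    members: list[ProductRecord]
    known_molecule_registry: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class Violation:
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.path}: {self.message}"


def _check_termset(terms, path: str, out: list[Violation]) -> None:
    normalized = [normalize_term(t) for t in terms]
    for t, n in zip(terms, normalized):
        if t != n:
            out.append(Violation(path, f"term {t!r} is not normalized"))
    if len(set(normalized)) < len(set(terms)):
        out.append(Violation(path, "terms collide after normalization"))


def validate_product(record: ProductRecord) -> list[Violation]:
    """Check every type invariant of a :class:`ProductRecord`.

    Returns one :class:`Violation` per breach, each with a dotted field path;
    an empty list means the record is valid.  Never mutates the input and
    never raises on invalid content.
    """
    v: list[Violation] = []
    if not normalize_term(record.brand_name):
        v.append(Violation("brand_name", "must be non-empty"))
    if not record.substances:
        v.append(Violation("substances", "at least one substance is required"))
    for i, sub in enumerate(record.substances):
        p = f"substances[{i}]"
        if not normalize_term(sub.inn_name):
            v.append(Violation(f"{p}.inn_name", "must be non-empty after normalization"))
        if (sub.strength_value is None) != (sub.strength_unit is None):
            v.append(
                Violation(p, "strength_value and strength_unit must be paired")
            )
        if sub.strength_value is not None and sub.strength_value < 0:
            v.append(Violation(f"{p}.strength_value", "must be non-negative"))
    if not normalize_term(record.pharmaceutical_form):
        v.append(Violation("pharmaceutical_form", "must be non-empty"))
    if not record.routes:
        v.append(Violation("routes", "at least one route is required"))
    else:
        _check_termset(record.routes, "routes", v)
    if not record.indications:
        v.append(Violation("indications", "at least one indication is required"))
    for i, ind in enumerate(record.indications):
        p = f"indications[{i}]"
        if not normalize_term(ind.condition_term):
            v.append(Violation(f"{p}.condition_term", "must be non-empty"))
        if ind.target_kind not in TARGET_KINDS:
            v.append(Violation(f"{p}.target_kind", f"must be one of {TARGET_KINDS}"))
        if ind.treatment_type not in TREATMENT_TYPES:
            v.append(
                Violation(f"{p}.treatment_type", f"must be one of {TREATMENT_TYPES}")
            )
        _check_termset(ind.coadministration_terms, f"{p}.coadministration_terms", v)
    d = record.dosing
    if (d.dose_per_intake_value is None) != (d.dose_per_intake_unit is None):
        v.append(Violation("dosing", "dose_per_intake value and unit must be paired"))
    if d.intakes_per_day is not None and d.intakes_per_day <= 0:
        v.append(Violation("dosing.intakes_per_day", "must be positive"))
    if d.duration_days is not None and d.duration_days <= 0:
        v.append(Violation("dosing.duration_days", "must be positive"))
    if d.units_per_intake is not None and (
        d.units_per_intake <= 0 or int(d.units_per_intake) != d.units_per_intake
    ):
        v.append(Violation("dosing.units_per_intake", "must be a positive integer"))
    for name in ("serious_adr_terms", "contraindication_terms", "serious_ddi_terms",
                 "monitoring_test_terms"):
        _check_termset(getattr(record, name), name, v)
    if record.overdose.risk_grade not in RISK_GRADES:
        v.append(Violation("overdose.risk_grade", f"must be one of {RISK_GRADES}"))
    if record.overdose.antidote_available not in YES_NO_UNKNOWN:
        v.append(
            Violation("overdose.antidote_available", f"must be one of {YES_NO_UNKNOWN}")
        )
    if record.invasiveness_grade not in INVASIVENESS_GRADES:
        v.append(
            Violation("invasiveness_grade", f"must be one of {INVASIVENESS_GRADES}")
        )
    if record.convenience_grade not in CONVENIENCE_GRADES:
        v.append(Violation("convenience_grade", f"must be one of {CONVENIENCE_GRADES}"))
    if record.dose_adjustability_grade not in ADJUSTABILITY_GRADES:
        v.append(
            Violation(
                "dose_adjustability_grade", f"must be one of {ADJUSTABILITY_GRADES}"
            )
        )
    return v


def validate_arsenal(arsenal: TherapeuticArsenal) -> list[Violation]:
    """Arsenal invariants: members share the arsenal's indication; the
    known-molecule registry covers every member INN."""
    v: list[Violation] = []
    cond = normalize_term(arsenal.indication.condition_term)
    for i, m in enumerate(arsenal.members):
        v.extend(
            Violation(f"members[{i}].{viol.path}", viol.message)
            for viol in validate_product(m)
        )
        if cond not in m.indication_terms():
            v.append(
                Violation(
                    f"members[{i}].indications",
                    f"member {m.brand_name!r} does not list {cond!r}",
                )
            )
        for sub in m.substances:
            if normalize_term(sub.inn_name) not in arsenal.known_molecule_registry:
                v.append(
                    Violation(
                        "known_molecule_registry",
                        f"missing member INN {normalize_term(sub.inn_name)!r}",
                    )
                )
    return v


# ---------------------------------------------------------------------------
# Document I/O — JSON canonical, YAML accepted.


def _sub_doc(s: Substance) -> dict:
    return {
        "inn_name": s.inn_name,
        "atc_code": s.atc_code,
        "strength_value": s.strength_value,
        "strength_unit": s.strength_unit,
    }


def _ind_doc(i: Indication) -> dict:
    return {
        "condition_term": i.condition_term,
        "target_kind": i.target_kind,
        "treatment_type": i.treatment_type,
        "coadministration_terms": sorted(i.coadministration_terms),
    }


def write_record(record: ProductRecord) -> dict:
    """Serialize a record to its canonical document form (plain dict with
    sorted term lists).  Inverse of :func:`read_record` on valid documents."""
    d = record.dosing
    return {
        "brand_name": record.brand_name,
        "substances": [_sub_doc(s) for s in record.substances],
        "pharmaceutical_form": record.pharmaceutical_form,
        "routes": sorted(record.routes),
        "presentation_term": record.presentation_term,
        "pharmacotherapeutic_group": record.pharmacotherapeutic_group,
        "mechanism_term": record.mechanism_term,
        "indications": [_ind_doc(i) for i in record.indications],
        "dosing": {
            "dose_per_intake_value": d.dose_per_intake_value,
            "dose_per_intake_unit": d.dose_per_intake_unit,
            "intakes_per_day": d.intakes_per_day,
            "duration_days": d.duration_days,
            "units_per_intake": d.units_per_intake,
        },
        "serious_adr_terms": sorted(record.serious_adr_terms),
        "contraindication_terms": sorted(record.contraindication_terms),
        "serious_ddi_terms": sorted(record.serious_ddi_terms),
        "overdose": {
            "risk_grade": record.overdose.risk_grade,
            "antidote_available": record.overdose.antidote_available,
        },
        "monitoring_test_terms": sorted(record.monitoring_test_terms),
        "invasiveness_grade": record.invasiveness_grade,
        "convenience_grade": record.convenience_grade,
        "dose_adjustability_grade": record.dose_adjustability_grade,
    }


def read_record(document: dict, schema_version: str = "v2") -> ProductRecord:
    """Parse a product document into a :class:`ProductRecord`.

    The document is first checked against the published JSON Schema for the
    requested version; structural problems raise :class:`ParseError` naming
    the offending path (distinct from invariant violations, which are the
    business of :func:`validate_product`).
    """
    errors = check_document(document, get_schema("product", schema_version))
    if errors:
        path, msg = errors[0]
        raise ParseError(path, msg)
    subs = [
        Substance(
            inn_name=s["inn_name"],
            atc_code=s.get("atc_code"),
            strength_value=s.get("strength_value"),
            strength_unit=s.get("strength_unit"),
        )
        for s in document["substances"]
    ]
    inds = [
        Indication(
            condition_term=i["condition_term"],
            target_kind=i["target_kind"],
            treatment_type=i["treatment_type"],
            coadministration_terms=set(i.get("coadministration_terms", [])),
        )
        for i in document["indications"]
    ]
    dd = document.get("dosing", {})
    od = document.get("overdose", {})
    return ProductRecord(
        brand_name=document["brand_name"],
        substances=subs,
        pharmaceutical_form=document["pharmaceutical_form"],
        routes=set(document["routes"]),
        presentation_term=document["presentation_term"],
        pharmacotherapeutic_group=document["pharmacotherapeutic_group"],
        mechanism_term=document["mechanism_term"],
        indications=inds,
        dosing=Dosing(
            dose_per_intake_value=dd.get("dose_per_intake_value"),
            dose_per_intake_unit=dd.get("dose_per_intake_unit"),
            intakes_per_day=dd.get("intakes_per_day"),
            duration_days=dd.get("duration_days"),
            units_per_intake=dd.get("units_per_intake"),
        ),
        serious_adr_terms=set(document.get("serious_adr_terms", [])),
        contraindication_terms=set(document.get("contraindication_terms", [])),
        serious_ddi_terms=set(document.get("serious_ddi_terms", [])),
        overdose=Overdose(
            risk_grade=od.get("risk_grade", "unknown"),
            antidote_available=od.get("antidote_available", "unknown"),
        ),
        monitoring_test_terms=set(document.get("monitoring_test_terms", [])),
        invasiveness_grade=document.get("invasiveness_grade", "unknown"),
        convenience_grade=document.get("convenience_grade", "unknown"),
        dose_adjustability_grade=document.get("dose_adjustability_grade", "unknown"),
    )


def arsenal_to_document(arsenal: TherapeuticArsenal) -> dict:
    return {
        "indication": _ind_doc(arsenal.indication),
        "members": [write_record(m) for m in arsenal.members],
        "known_molecule_registry": sorted(arsenal.known_molecule_registry),
    }


def arsenal_from_document(document: dict, schema_version: str = "v2") -> TherapeuticArsenal:
    errors = check_document(document, get_schema("arsenal", schema_version))
    if errors:
        path, msg = errors[0]
        raise ParseError(path, msg)
    i = document["indication"]
    return TherapeuticArsenal(
        indication=Indication(
            condition_term=i["condition_term"],
            target_kind=i["target_kind"],
            treatment_type=i["treatment_type"],
            coadministration_terms=set(i.get("coadministration_terms", [])),
        ),
        members=[read_record(m, schema_version) for m in document["members"]],
        known_molecule_registry=set(document["known_molecule_registry"]),
    )


def canonical_json(document) -> str:
    """Canonical serialization: sorted keys, two-space indent, trailing
    newline.  Identical inputs give byte-identical output, so artifacts are
    diffable in tests."""
    return json.dumps(document, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def load_document(path: str) -> dict:
    """Load a JSON (canonical) or YAML (accepted) document from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    try:
        if path.endswith((".yaml", ".yml")):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError("$", f"unreadable document: {exc}") from exc
    if not isinstance(doc, (dict, list)):
        raise ParseError("$", "document root must be an object or array")
    return doc
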