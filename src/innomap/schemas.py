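"""JSON Schemas for product and arsenal documents, in two model versions.

Version ``v1`` is the model as first designed; ``v2`` (the default) adds a
single element under dosing — the duration of administration — which the
completeness analysis of the model surfaced as the only SPC feature the v1
model could not represent.  The v1 dosing object is deliberately open
(``additionalProperties: true``): an unmodeled attribute in an input document
is not a parse failure but a *coverage gap*, which :func:`schema_coverage`
reports.

A small structural checker (:func:`check_document`) enforces the schemas at
read time: type/enum/required/additionalProperties/minItems/minimum, which is
the subset these schemas use.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = [
    "ParseError",
    "SCHEMA_VERSIONS",
    "check_document",
    "get_schema",
    "schema_coverage",
    "write_schema_files",
]

SCHEMA_VERSIONS = ("v1", "v2")


class ParseError(ValueError):
    """A document does not conform to its schema (or is unreadable).

    Distinct from record-invariant violations: a parse error means the
    document could not be interpreted at all; a validation violation means a
    well-formed record breaks a domain invariant.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        self.message = message
        super().__init__(f"{path}: {message}")


def _nullable(t: str, **extra) -> dict:
    return {"type": [t, "null"], **extra}


_SUBSTANCE = {
    "type": "object",
    "required": ["inn_name"],
    "additionalProperties": False,
    "properties": {
        "inn_name": {"type": "string"},
        "atc_code": _nullable("string"),
        "strength_value": _nullable("number", minimum=0),
        "strength_unit": _nullable("string"),
    },
}

_INDICATION = {
    "type": "object",
    "required": ["condition_term", "target_kind", "treatment_type"],
    "additionalProperties": False,
    "properties": {
        "condition_term": {"type": "string"},
        "target_kind": {"type": "string", "enum": ["disease", "symptom", "risk_factor"]},
        "treatment_type": {
            "type": "string",
            "enum": ["curative", "symptomatic", "substitutive", "preventive"],
        },
        "coadministration_terms": {"type": "array", "items": {"type": "string"}},
    },
}


def _dosing_schema(version: str) -> dict:
    props = {
        "dose_per_intake_value": _nullable("number", minimum=0),
        "dose_per_intake_unit": _nullable("string"),
        "intakes_per_day": _nullable("number", exclusiveMinimum=0),
        "units_per_intake": _nullable("integer", exclusiveMinimum=0),
    }
    if version == "v2":
        props["duration_days"] = _nullable("number", exclusiveMinimum=0)
    return {
        "type": "object",
        # v1 predates the duration element; unmodeled keys there are coverage
        # gaps, not parse failures.
        "additionalProperties": version == "v1",
        "properties": props,
    }


def _termset() -> dict:
    return {"type": "array", "items": {"type": "string"}}


def _product_schema(version: str) -> dict:
    return {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": f"https://innomap.invalid/schemas/product.{version}.json",
        "title": f"ProductRecord ({version})",
        "type": "object",
        "required": [
            "brand_name",
            "substances",
            "pharmaceutical_form",
            "routes",
            "presentation_term",
            "pharmacotherapeutic_group",
            "mechanism_term",
            "indications",
        ],
        "additionalProperties": False,
        "properties": {
            "brand_name": {"type": "string"},
            "substances": {"type": "array", "minItems": 1, "items": _SUBSTANCE},
            "pharmaceutical_form": {"type": "string"},
            "routes": {"type": "array", "minItems": 1, "items": {"type": "string"}},
            "presentation_term": {"type": "string"},
            "pharmacotherapeutic_group": {"type": "string"},
            "mechanism_term": {"type": "string"},
            "indications": {"type": "array", "minItems": 1, "items": _INDICATION},
            "dosing": _dosing_schema(version),
            "serious_adr_terms": _termset(),
            "contraindication_terms": _termset(),
            "serious_ddi_terms": _termset(),
            "overdose": {
                "type": "object",
                "additionalProperties": False,
                "properties": {
                    "risk_grade": {
                        "type": "string",
                        "enum": ["low", "moderate", "high", "unknown"],
                    },
                    "antidote_available": {
                        "type": "string",
                        "enum": ["yes", "no", "unknown"],
                    },
                },
            },
            "monitoring_test_terms": _termset(),
            "invasiveness_grade": {
                "type": "string",
                "enum": ["noninvasive", "minimally_invasive", "invasive", "unknown"],
            },
            "convenience_grade": {
                "type": "string",
                "enum": ["low", "medium", "high", "unknown"],
            },
            "dose_adjustability_grade": {
                "type": "string",
                "enum": ["easy", "moderate", "difficult", "unknown"],
            },
        },
    }


def _arsenal_schema(version: str) -> dict:
    return {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": f"https://innomap.invalid/schemas/arsenal.{version}.json",
        "title": f"TherapeuticArsenal ({version})",
        "type": "object",
        "required": ["indication", "members", "known_molecule_registry"],
        "additionalProperties": False,
        "properties": {
            "indication": _INDICATION,
            "members": {"type": "array", "items": _product_schema(version)},
            "known_molecule_registry": {"type": "array", "items": {"type": "string"}},
        },
    }


def get_schema(kind: str, version: str = "v2") -> dict:
    if version not in SCHEMA_VERSIONS:
        raise ValueError(f"unknown schema version {version!r}")
    if kind == "product":
        return _product_schema(version)
    if kind == "arsenal":
        return _arsenal_schema(version)
    raise ValueError(f"unknown record kind {kind!r}")


def write_schema_files(directory=None) -> list[str]:
    """Write the published ``<kind>.<version>.json`` schema files.

    Defaults to the package's own ``schemas/`` directory; used to (re)generate
    the shipped files."""
    if directory is None:
        directory = resources.files("innomap") / "schemas"
    written = []
    for kind in ("product", "arsenal"):
        for version in SCHEMA_VERSIONS:
            path = directory / f"{kind}.{version}.json"
            with open(str(path), "w", encoding="utf-8") as fh:
                json.dump(get_schema(kind, version), fh, indent=2, sort_keys=True)
                fh.write("\n")
            written.append(str(path))
    return written


# ---------------------------------------------------------------------------
# Structural checking


def _type_ok(value, types: list[str]) -> bool:
    for t in types:
        if t == "null" and value is None:
            return True
        if t == "string" and isinstance(value, str):
            return True
        if t == "boolean" and isinstance(value, bool):
            return True
        if t == "integer" and isinstance(value, int) and not isinstance(value, bool):
            return True
        if (
            t == "number"
            and isinstance(value, (int, float))
            and not isinstance(value, bool)
        ):
            return True
        if t == "object" and isinstance(value, dict):
            return True
        if t == "array" and isinstance(value, list):
            return True
    return False


def check_document(document, schema: dict, path: str = "$") -> list[tuple[str, str]]:
    """Check a document against a schema; returns ``(path, message)`` pairs,
    empty when conformant."""
    errors: list[tuple[str, str]] = []
    _check(document, schema, path, errors)
    return errors


def _check(value, schema: dict, path: str, errors: list) -> None:
    t = schema.get("type")
    if t is not None:
        types = t if isinstance(t, list) else [t]
        if not _type_ok(value, types):
            errors.append((path, f"expected {' or '.join(types)}"))
            return
    if value is None:
        return
    if "enum" in schema and value not in schema["enum"]:
        errors.append((path, f"must be one of {schema['enum']}"))
        return
    if isinstance(value, dict):
        props = schema.get("properties", {})
        for req in schema.get("required", ()):
            if req not in value:
                errors.append((f"{path}.{req}", "required property is missing"))
        for key, item in value.items():
            if key in props:
                _check(item, props[key], f"{path}.{key}", errors)
            elif schema.get("additionalProperties") is False:
                errors.append((f"{path}.{key}", "unexpected property"))
    elif isinstance(value, list):
        if "minItems" in schema and len(value) < schema["minItems"]:
            errors.append((path, f"requires at least {schema['minItems']} item(s)"))
        items = schema.get("items")
        if items:
            for i, item in enumerate(value):
                _check(item, items, f"{path}[{i}]", errors)
    elif isinstance(value, (int, float)) and not isinstance(value, bool):
        if "minimum" in schema and value < schema["minimum"]:
            errors.append((path, f"must be >= {schema['minimum']}"))
        excl = schema.get("exclusiveMinimum")
        if excl is not None and value <= excl:
            errors.append((path, f"must be > {excl}"))


# ---------------------------------------------------------------------------
# Coverage scanning (completeness analysis)


def _has_content(value) -> bool:
    if value is None:
        return False
    if isinstance(value, (list, dict)) and not value:
        return False
    return True


def _scan(value, schema: dict, path: str, unmapped: set) -> None:
    if isinstance(value, dict):
        props = schema.get("properties", {})
        for key, item in value.items():
            key_path = f"{path}.{key}" if path else key
            if key in props:
                _scan(item, props[key], key_path, unmapped)
            elif _has_content(item):
                unmapped.add(key_path)
    elif isinstance(value, list):
        items = schema.get("items") or {}
        for item in value:
            _scan(item, items, f"{path}[]", unmapped)


def schema_coverage(documents, version: str = "v2") -> list[str]:
    """Scan product documents for attributes the model version cannot
    represent.

    Returns the sorted dotted paths of populated attributes with no slot in
    the schema — the machine analogue of reading SPCs against the model and
    listing the innovative features it fails to capture.
    """
    schema = get_schema("product", version)
    unmapped: set[str] = set()
    for doc in documents:
        _scan(doc, schema, "", unmapped)
    return sorted(unmapped)
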