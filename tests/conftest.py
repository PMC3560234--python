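import random

import pytest

from innomap.fixtures import efient_fixture, epipen_fixture
from innomap.model import (
    Dosing,
    Indication,
    Overdose,
    ProductRecord,
    Substance,
    TherapeuticArsenal,
)


@pytest.fixture
def efient():
    return efient_fixture()


@pytest.fixture
def epipen():
    return epipen_fixture()


def make_member(
    inn: str,
    indication: Indication,
    route: str = "oral",
    form: str = "tablet",
    presentation: str = "blister pack",
    mechanism: str = "mech-a",
    group: str = "group-a",
    dose: float = 10.0,
    brand: str | None = None,
    substances=None,
) -> ProductRecord:
    return ProductRecord(
        brand_name=brand or f"brand-{inn}",
        substances=substances
        or [Substance(inn_name=inn, strength_value=dose, strength_unit="mg")],
        pharmaceutical_form=form,
        routes={route},
        presentation_term=presentation,
        pharmacotherapeutic_group=group,
        mechanism_term=mechanism,
        indications=[indication],
        dosing=Dosing(
            dose_per_intake_value=dose,
            dose_per_intake_unit="mg",
            intakes_per_day=1.0,
            units_per_intake=1,
        ),
        overdose=Overdose(risk_grade="low", antidote_available="no"),
        invasiveness_grade="noninvasive",
    )


@pytest.fixture
def simple_indication():
    return Indication(
        condition_term="hypertension",
        target_kind="risk_factor",
        treatment_type="symptomatic",
    )


@pytest.fixture
def simple_arsenal(simple_indication):
    a = make_member("amlodipine", simple_indication)
    b = make_member(
        "lisinopril",
        simple_indication,
        route="oral",
        form="capsule",
        presentation="bottle",
        mechanism="mech-b",
        group="group-b",
        dose=5.0,
    )
    return TherapeuticArsenal(
        indication=simple_indication,
        members=[a, b],
        known_molecule_registry={"amlodipine", "lisinopril", "hydrochlorothiazide"},
    )


def random_record(rng: random.Random, indication: Indication, brand: str) -> ProductRecord:
    """A valid record with randomized comparison-relevant attributes."""
    terms = [f"term-{i:02d}" for i in range(6)]

    def termset():
        return set(rng.sample(terms, rng.randint(0, 3)))

    def maybe(value):
        return value if rng.random() < 0.7 else None

    dose = maybe(float(rng.choice([1, 2, 5, 10])))
    return ProductRecord(
        brand_name=brand,
        substances=[
            Substance(
                inn_name=rng.choice(["molecule-a", "molecule-b"]),
                strength_value=10.0,
                strength_unit="mg",
            )
        ],
        pharmaceutical_form=rng.choice(["tablet", "capsule"]),
        routes={rng.choice(["oral", "intravenous"])},
        presentation_term=rng.choice(["blister pack", "vial"]),
        pharmacotherapeutic_group="group-x",
        mechanism_term="mech-x",
        indications=[indication],
        dosing=Dosing(
            dose_per_intake_value=dose,
            dose_per_intake_unit="mg" if dose is not None else None,
            intakes_per_day=maybe(float(rng.randint(1, 4))),
            duration_days=maybe(float(rng.randint(1, 30))),
            units_per_intake=maybe(rng.randint(1, 3)),
        ),
        serious_adr_terms=termset(),
        contraindication_terms=termset(),
        serious_ddi_terms=termset(),
        overdose=Overdose(
            risk_grade=rng.choice(["low", "moderate", "high", "unknown"]),
            antidote_available=rng.choice(["yes", "no", "unknown"]),
        ),
        monitoring_test_terms=termset(),
        invasiveness_grade=rng.choice(
            ["noninvasive", "minimally_invasive", "invasive", "unknown"]
        ),
        convenience_grade=rng.choice(["low", "medium", "high", "unknown"]),
        dose_adjustability_grade=rng.choice(
            ["easy", "moderate", "difficult", "unknown"]
        ),
    )
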