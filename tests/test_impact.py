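"""Impact comparator: verdict conventions, antisymmetry, summaries."""

import itertools
import random

import pytest

from innomap.impact import (
    DIRECTIONS,
    ENDPOINT_CATEGORIES,
    EfficacyEvidence,
    ImpactItem,
    aggregate_impact,
    compare_ease_of_use,
    compare_efficacy,
    compare_item_sets,
    compare_safety,
    summarize_dimension,
)
from innomap.model import Overdose

from conftest import random_record


class TestItemSets:
    def test_identical_sets_are_all_equivalent(self):
        items = compare_item_sets({"a", "b"}, {"a", "b"}, "serious_adr")
        assert [i.verdict for i in items] == ["equivalent", "equivalent"]

    def test_empty_sets_emit_nothing(self):
        assert compare_item_sets(set(), set(), "serious_adr") == []

    def test_mixed_sets_follow_the_harm_direction_convention(self):
        items = {
            i.item_term: i.verdict
            for i in compare_item_sets({"a", "b"}, {"b", "c"}, "contraindication")
        }
        assert items == {"a": "negative", "b": "equivalent", "c": "positive"}

    @pytest.mark.parametrize("in_new", [True, False])
    @pytest.mark.parametrize("in_cmp", [True, False])
    def test_every_membership_pattern(self, in_new, in_cmp):
        """All 2^2 per-term membership patterns against the stated
        convention: new-only terms are extra harms (negative)."""
        new = {"t"} if in_new else set()
        cmp_ = {"t"} if in_cmp else set()
        items = compare_item_sets(new, cmp_, "serious_ddi")
        if not in_new and not in_cmp:
            assert items == []
        else:
            expected = (
                "equivalent" if in_new and in_cmp
                else "negative" if in_new
                else "positive"
            )
            assert [i.verdict for i in items] == [expected]


class TestOverdose:
    @pytest.mark.parametrize(
        "new_grade,cmp_grade",
        list(itertools.product(["low", "moderate", "high"], repeat=2)),
    )
    @pytest.mark.parametrize(
        "new_ant,cmp_ant", list(itertools.product(["yes", "no"], repeat=2))
    )
    def test_full_grade_by_antidote_table(
        self, efient, new_grade, cmp_grade, new_ant, cmp_ant
    ):
        """Enumerate the 3x3 risk-grade x 2x2 antidote table against an
        independent restatement of the ordering rules."""
        new = efient.new
        comparator = efient.comparator
        new.overdose = Overdose(new_grade, new_ant)
        comparator.overdose = Overdose(cmp_grade, cmp_ant)
        item = [
            i for i in compare_safety(new, comparator) if i.subcategory == "overdose"
        ][0]

        order = {"low": 0, "moderate": 1, "high": 2}
        risk_better = order[cmp_grade] - order[new_grade]  # >0: new risks less
        ant_better = {"no": 0, "yes": 1}[new_ant] - {"no": 0, "yes": 1}[cmp_ant]
        if risk_better == 0 and ant_better == 0:
            expected = "equivalent"
        elif risk_better * ant_better < 0:
            expected = "not_assessable"
        elif risk_better > 0 or ant_better > 0:
            expected = "positive"
        else:
            expected = "negative"
        assert item.verdict == expected

    def test_one_sided_unknown_grade_is_not_assessable(self, efient):
        efient.new.overdose = Overdose("unknown", "yes")
        efient.comparator.overdose = Overdose("low", "yes")
        item = [
            i
            for i in compare_safety(efient.new, efient.comparator)
            if i.subcategory == "overdose"
        ][0]
        assert item.verdict == "not_assessable"

    def test_antidote_in_favour_of_the_new_product(self, efient):
        efient.new.overdose = Overdose("moderate", "yes")
        efient.comparator.overdose = Overdose("moderate", "no")
        item = [
            i
            for i in compare_safety(efient.new, efient.comparator)
            if i.subcategory == "overdose"
        ][0]
        assert item.verdict == "positive"


class TestEfficacy:
    @pytest.mark.parametrize("category", ENDPOINT_CATEGORIES)
    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_all_direction_endpoint_combinations(self, category, direction):
        item = compare_efficacy(EfficacyEvidence(category, direction))
        expected = {
            "superior": "positive",
            "non_inferior": "equivalent",
            "inferior": "negative",
            "not_assessable": "not_assessable",
        }[direction]
        assert item.verdict == expected
        assert item.subcategory == category
        assert item.dimension == "efficacy"

    def test_prevention_of_complications_superiority_is_positive(self):
        item = compare_efficacy(
            EfficacyEvidence("prevention.complications", "superior")
        )
        assert item.verdict == "positive"

    def test_invalid_enumerations_are_rejected(self):
        with pytest.raises(ValueError):
            EfficacyEvidence("vibes", "superior")
        with pytest.raises(ValueError):
            EfficacyEvidence("symptomatology", "better")


class TestEaseOfUse:
    def test_fewer_monitoring_tests_is_positive(self, efient):
        efient.comparator.monitoring_test_terms = {"anti-xa activity", "platelet count"}
        efient.new.monitoring_test_terms = set()
        items = {
            i.subcategory: i.verdict
            for i in compare_ease_of_use(efient.new, efient.comparator)
        }
        assert items["monitoring"] == "positive"

    def test_attribute_identical_records_are_all_equivalent(self, efient):
        items = compare_ease_of_use(efient.comparator, efient.comparator)
        assert {i.verdict for i in items} == {"equivalent"}

    def test_numeric_verdicts_equal_a_sign_oracle(self, simple_indication):
        for seed in range(60):
            rng = random.Random(seed)
            a = random_record(rng, simple_indication, "a")
            b = random_record(rng, simple_indication, "b")
            items = {i.subcategory: i for i in compare_ease_of_use(a, b)}
            for sub, av, bv in [
                ("units_per_intake", a.dosing.units_per_intake, b.dosing.units_per_intake),
                ("intakes_per_day", a.dosing.intakes_per_day, b.dosing.intakes_per_day),
                ("duration_days", a.dosing.duration_days, b.dosing.duration_days),
                (
                    "monitoring",
                    len(a.monitoring_test_terms),
                    len(b.monitoring_test_terms),
                ),
            ]:
                if av == bv:
                    expected = "equivalent"
                elif av is None or bv is None:
                    expected = "not_assessable"
                else:
                    expected = "positive" if av < bv else "negative"
                assert items[sub].verdict == expected, (seed, sub)


def _swap_verdict(v: str) -> str:
    return {"positive": "negative", "negative": "positive"}.get(v, v)


class TestProfileProperties:
    def test_swapping_the_products_flips_every_verdict(self, simple_indication):
        """Antisymmetry: positive <-> negative under product swap;
        equivalent and not_assessable are fixed points."""
        for seed in range(40):
            rng = random.Random(1000 + seed)
            a = random_record(rng, simple_indication, "a")
            b = random_record(rng, simple_indication, "b")
            forward = compare_safety(a, b) + compare_ease_of_use(a, b)
            backward = compare_safety(b, a) + compare_ease_of_use(b, a)
            fwd = {(i.subcategory, i.item_term): i.verdict for i in forward}
            bwd = {(i.subcategory, i.item_term): i.verdict for i in backward}
            assert fwd.keys() == bwd.keys()
            for key, verdict in fwd.items():
                assert bwd[key] == _swap_verdict(verdict), (seed, key)

    def test_aggregate_antisymmetry_with_flipped_evidence(self, efient):
        evidence = list(efient.evidence)
        forward = aggregate_impact(efient.new, efient.comparator, evidence)
        backward = aggregate_impact(
            efient.comparator, efient.new, [e.flipped() for e in evidence]
        )
        fwd = sorted((i.subcategory, i.item_term, i.verdict) for i in forward.items)
        bwd = sorted(
            (i.subcategory, i.item_term, _swap_verdict(i.verdict))
            for i in backward.items
        )
        assert fwd == bwd

    def test_self_comparison_yields_no_impact_everywhere(self, efient, epipen):
        for record in (efient.new, efient.comparator, epipen.product):
            profile = aggregate_impact(
                record, record, [EfficacyEvidence("symptomatology", "non_inferior")]
            )
            assert all(i.verdict == "equivalent" for i in profile.items)
            assert set(profile.dimension_summaries.values()) == {"no_impact"}

    def test_verdict_enumeration_is_closed(self, simple_indication):
        allowed = {"positive", "equivalent", "negative", "not_assessable"}
        for seed in range(20):
            rng = random.Random(2000 + seed)
            a = random_record(rng, simple_indication, "a")
            b = random_record(rng, simple_indication, "b")
            profile = aggregate_impact(a, b)
            assert {i.verdict for i in profile.items} <= allowed

    def test_summaries_equal_independent_recomputation(self, simple_indication):
        for seed in range(30):
            rng = random.Random(3000 + seed)
            a = random_record(rng, simple_indication, "a")
            b = random_record(rng, simple_indication, "b")
            profile = aggregate_impact(a, b)
            for dim, summary in profile.dimension_summaries.items():
                verdicts = [i.verdict for i in profile.items if i.dimension == dim]
                if all(v == "equivalent" for v in verdicts):
                    expected = "no_impact"
                elif any(v in ("positive", "negative") for v in verdicts):
                    expected = "impact"
                else:
                    expected = "not_assessable"
                assert summary == expected

    def test_no_impact_iff_every_item_equivalent(self):
        eq = ImpactItem("safety", "serious_adr", "x", "equivalent")
        na = ImpactItem("safety", "serious_adr", "y", "not_assessable", "unknown")
        assert summarize_dimension([]) == "no_impact"
        assert summarize_dimension([eq, eq]) == "no_impact"
        assert summarize_dimension([eq, na]) == "not_assessable"

    def test_non_equivalent_items_require_a_rationale(self):
        with pytest.raises(ValueError):
            ImpactItem("safety", "serious_adr", "x", "negative", rationale="")
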