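"""Novelty classifier: precedence, scoped flags, oracle equivalence,
monotonicity."""

import copy
import itertools
import random

import pytest

from innomap.fixtures import GeneratorConfig, generate_arsenal
from innomap.model import (
    ContractError,
    Indication,
    ProductRecord,
    Substance,
    TherapeuticArsenal,
    normalize_term,
)
from innomap.novelty import (
    TOP_LEVELS,
    classify_top_level,
    detect_indication_novelty,
    detect_mechanism_novelty,
    detect_usage_novelty,
    summarize_novelty,
    tally_novelty,
)

from conftest import make_member


# ---------------------------------------------------------------------------
# Top level


class TestTopLevel:
    @pytest.mark.parametrize("in_reg_1", [True, False])
    @pytest.mark.parametrize("in_reg_2", [True, False, None])  # None: single substance
    @pytest.mark.parametrize("combo_marketed", [True, False])
    def test_matches_precedence_rule_for_all_membership_patterns(
        self, simple_indication, in_reg_1, in_reg_2, combo_marketed
    ):
        """Brute-force enumeration of registry/arsenal membership for <=2
        substances against the precedence new_molecule > new_combination >
        known_molecule."""
        subs = [Substance("mol-1", strength_value=1.0, strength_unit="mg")]
        registry = set()
        if in_reg_1:
            registry.add("mol-1")
        if in_reg_2 is not None:
            subs.append(Substance("mol-2", strength_value=1.0, strength_unit="mg"))
            if in_reg_2:
                registry.add("mol-2")
        members = [make_member("mol-1", simple_indication)]
        registry.add("mol-1")  # arsenal invariant: registry covers members
        if combo_marketed and len(subs) == 2:
            members.append(
                make_member(
                    "mol-1",
                    simple_indication,
                    brand="brand-combo",
                    substances=[Substance("mol-1"), Substance("mol-2")],
                )
            )
            registry.add("mol-2")
        arsenal = TherapeuticArsenal(
            indication=simple_indication,
            members=members,
            known_molecule_registry=registry,
        )
        product = make_member(
            "mol-1", simple_indication, brand="candidate", substances=subs
        )

        # independent oracle: restate the definition
        any_unknown = any(
            normalize_term(s.inn_name) not in registry for s in subs
        )
        if any_unknown:
            expected = "new_molecule"
        elif len(subs) > 1 and not any(
            sorted(normalize_term(x.inn_name) for x in m.substances)
            == sorted(normalize_term(x.inn_name) for x in subs)
            for m in members
        ):
            expected = "new_combination"
        else:
            expected = "known_molecule"

        assert classify_top_level(product, arsenal) == expected

    def test_unvalidated_product_is_a_contract_error(self, simple_arsenal):
        bad = make_member("amlodipine", simple_arsenal.indication)
        bad.substances = []
        with pytest.raises(ContractError):
            classify_top_level(bad, simple_arsenal)

    def test_totality_and_uniqueness_over_random_inputs(self):
        for seed in range(40):
            arsenal = generate_arsenal(GeneratorConfig(seed=seed, n_members=3))
            product = copy.deepcopy(arsenal.members[seed % 3])
            product.brand_name = "candidate"
            if seed % 2:
                product.substances = [Substance(f"fresh-{seed}")]
            assert classify_top_level(product, arsenal) in TOP_LEVELS


# ---------------------------------------------------------------------------
# Mechanism / group


class TestMechanismNovelty:
    def test_term_shared_with_a_member_is_not_novel(self, simple_arsenal):
        product = make_member("amlodipine", simple_arsenal.indication)
        new_mech, new_group = detect_mechanism_novelty(product, simple_arsenal)
        assert (new_mech, new_group) == (False, False)

    def test_empty_arsenal_makes_both_flags_vacuously_true(self, simple_indication):
        empty = TherapeuticArsenal(
            indication=simple_indication, members=[], known_molecule_registry=set()
        )
        product = make_member("anything", simple_indication)
        assert detect_mechanism_novelty(product, empty) == (True, True)

    def test_flags_equal_naive_union_oracle_on_random_arsenals(self):
        for seed in range(30):
            rng = random.Random(seed)
            arsenal = generate_arsenal(GeneratorConfig(seed=seed, n_members=4))
            product = copy.deepcopy(arsenal.members[0])
            product.mechanism_term = rng.choice(
                [m.mechanism_term for m in arsenal.members] + ["mechanism-zz"]
            )
            product.pharmacotherapeutic_group = rng.choice(
                [m.pharmacotherapeutic_group for m in arsenal.members] + ["group-zz"]
            )
            expected = (
                product.mechanism_term
                not in {m.mechanism_term for m in arsenal.members},
                product.pharmacotherapeutic_group
                not in {m.pharmacotherapeutic_group for m in arsenal.members},
            )
            assert detect_mechanism_novelty(product, arsenal) == expected


# ---------------------------------------------------------------------------
# Usage flags


def _usage_oracle(product, arsenal):
    """Independent restatement of the scoped membership definitions."""
    sharing = [
        m
        for m in arsenal.members
        if {s.inn_name for s in m.substances} & {s.inn_name for s in product.substances}
    ]
    route_sharing = [m for m in arsenal.members if m.routes & product.routes]
    return {
        "route_mol": not any(product.routes & m.routes for m in sharing),
        "route_ars": not any(product.routes & m.routes for m in arsenal.members),
        "form_mol": product.pharmaceutical_form
        not in [m.pharmaceutical_form for m in sharing],
        "form_route": product.pharmaceutical_form
        not in [m.pharmaceutical_form for m in route_sharing],
        "form_ars": product.pharmaceutical_form
        not in [m.pharmaceutical_form for m in arsenal.members],
        "dose": product.dosing.dose()
        not in [m.dosing.dose() for m in sharing],
        "presentation": product.presentation_term
        not in [m.presentation_term for m in sharing],
        "protocol": product.dosing.protocol_triple()
        not in [m.dosing.protocol_triple() for m in sharing],
    }


class TestUsageNovelty:
    def test_exhaustive_two_member_arsenals_match_the_oracle(self, simple_indication):
        """All 2-member arsenals over two-valued attribute vocabularies,
        against a naive membership oracle."""
        inns = ["mol-1", "mol-2"]
        routes = ["oral", "nasal"]
        forms = ["tablet", "spray"]
        n = 0
        for m1_attrs, m2_attrs, p_attrs in itertools.product(
            itertools.product(inns, routes, forms), repeat=3
        ):
            members = [
                make_member(a[0], simple_indication, route=a[1], form=a[2],
                            brand=f"m{i}")
                for i, a in enumerate([m1_attrs, m2_attrs])
            ]
            arsenal = TherapeuticArsenal(
                indication=simple_indication,
                members=members,
                known_molecule_registry={"mol-1", "mol-2"},
            )
            product = make_member(
                p_attrs[0], simple_indication, route=p_attrs[1], form=p_attrs[2],
                brand="candidate",
            )
            got = detect_usage_novelty(product, arsenal)
            want = _usage_oracle(product, arsenal)
            assert (
                got.new_route.for_molecule,
                got.new_route.for_arsenal,
                got.new_form.for_molecule,
                got.new_form.for_route,
                got.new_form.for_arsenal,
            ) == (
                want["route_mol"],
                want["route_ars"],
                want["form_mol"],
                want["form_route"],
                want["form_ars"],
            )
            assert got.new_dose == want["dose"]
            assert got.new_presentation == want["presentation"]
            assert got.new_protocol == want["protocol"]
            n += 1
        assert n == 8**3

    def test_attribute_twin_of_a_member_has_no_usage_novelty(self, simple_arsenal):
        twin = copy.deepcopy(simple_arsenal.members[0])
        twin.brand_name = "twin"
        got = detect_usage_novelty(twin, simple_arsenal)
        assert not any(
            [
                got.new_route.for_molecule,
                got.new_route.for_arsenal,
                got.new_form.for_molecule,
                got.new_form.for_route,
                got.new_form.for_arsenal,
                got.new_dose,
                got.new_presentation,
                got.new_protocol,
            ]
        )

    def test_route_novel_for_molecule_but_not_for_arsenal(self, simple_arsenal):
        product = copy.deepcopy(simple_arsenal.members[0])
        product.brand_name = "candidate"
        simple_arsenal.members[1].routes = {"intravenous"}
        product.routes = {"intravenous"}
        got = detect_usage_novelty(product, simple_arsenal)
        assert got.new_route.for_molecule and not got.new_route.for_arsenal

    def test_autoinjector_presentation_is_the_only_novelty(self, epipen):
        got = detect_usage_novelty(epipen.product, epipen.arsenal)
        assert got.new_presentation
        assert not (
            got.new_route.for_molecule
            or got.new_form.for_molecule
            or got.new_dose
            or got.new_protocol
        )


# ---------------------------------------------------------------------------
# Indication novelty


class TestIndicationNovelty:
    def test_identical_label_sets_are_not_novel(self, efient):
        assert not detect_indication_novelty(
            efient.new, list(efient.new.indications)
        )

    def test_one_added_condition_is_novel(self, efient):
        extended = copy.deepcopy(efient.new)
        extended.indications.append(
            Indication("peripheral arterial disease", "disease", "preventive")
        )
        assert detect_indication_novelty(extended, list(efient.new.indications))

    def test_matches_set_difference_oracle_on_random_label_sets(
        self, simple_indication
    ):
        conditions = [f"condition-{i}" for i in range(5)]
        for seed in range(50):
            rng = random.Random(seed)
            current = rng.sample(conditions, rng.randint(1, 4))
            prior = rng.sample(conditions, rng.randint(0, 4))
            product = make_member("mol-1", simple_indication)
            product.indications = [
                Indication(c, "disease", "curative") for c in current
            ]
            labels = [Indication(c, "disease", "curative") for c in prior]
            assert detect_indication_novelty(product, labels) == bool(
                set(current) - set(prior)
            )


# ---------------------------------------------------------------------------
# Composition, monotonicity, tallies


class TestSummarize:
    def test_autoinjector_profile(self, epipen):
        profile = summarize_novelty(
            epipen.product, epipen.arsenal, list(epipen.prior_labels)
        )
        assert profile.top_level == "known_molecule"
        assert profile.new_presentation
        assert not profile.new_dose and not profile.new_protocol
        assert not profile.new_route.for_molecule
        assert not profile.new_form.for_molecule
        assert not profile.new_indication_or_extension

    def test_twin_of_member_has_all_flags_false(self, simple_arsenal):
        twin = copy.deepcopy(simple_arsenal.members[0])
        twin.brand_name = "twin"
        profile = summarize_novelty(
            twin, simple_arsenal, list(twin.indications)
        )
        assert profile.top_level == "known_molecule"
        assert not any(profile.flags().values())

    def test_enlarging_the_arsenal_never_creates_novelty(self):
        """Novelty can only shrink as the arsenal grows: every detector flag
        true against the enlarged arsenal is true against the smaller one."""
        for seed in range(30):
            big = generate_arsenal(GeneratorConfig(seed=seed, n_members=5))
            small = TherapeuticArsenal(
                indication=big.indication,
                members=big.members[:2],
                known_molecule_registry=big.known_molecule_registry,
            )
            product = copy.deepcopy(big.members[seed % 5])
            product.brand_name = "candidate"
            p_small = summarize_novelty(product, small, list(product.indications))
            p_big = summarize_novelty(product, big, list(product.indications))
            for name, value in p_big.flags().items():
                if name == "known_combination_new_form":
                    continue  # derived from the (mutable) top level
                if value:
                    assert p_small.flags()[name], f"{name} appeared on growth"

    def test_tally_counts_equal_brute_force_and_partition_input(self):
        profiles = []
        for seed in range(25):
            arsenal = generate_arsenal(GeneratorConfig(seed=seed, n_members=3))
            product = copy.deepcopy(arsenal.members[0])
            product.brand_name = "candidate"
            if seed % 3 == 0:
                product.substances = [Substance(f"fresh-{seed}")]
            profiles.append(
                summarize_novelty(product, arsenal, list(product.indications))
            )
        tally = tally_novelty(profiles)
        assert sum(tally["top_level"].values()) == len(profiles) == tally["n"]
        for cat in TOP_LEVELS:
            assert tally["top_level"][cat] == sum(
                p.top_level == cat for p in profiles
            )
        for flag, count in tally["flags"].items():
            assert count == sum(p.flags()[flag] for p in profiles)
            assert count <= len(profiles)

    def test_empty_tally_is_all_zero(self):
        tally = tally_novelty([])
        assert tally["n"] == 0
        assert set(tally["top_level"].values()) == {0}
        assert tally["flags"] == {}
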