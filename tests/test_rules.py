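"""Biotransformation catalog, gating, and metabolite enumeration."""

from collections import Counter

import pytest

from phasemet.chem import monoisotopic_mass, parse_formula
from phasemet.rules import (
    apply_rule,
    enumerate_metabolites,
    get_compound,
    load_compounds,
    root_candidate,
    rule_catalog,
    rule_delta_mass,
)

RULES = {r.id: r for r in rule_catalog()}


class TestCatalog:
    def test_catalog_has_eleven_rules(self):
        assert len(rule_catalog()) == 11
        assert len({r.id for r in rule_catalog()}) == 11

    def test_provisional_benzamide_hydrolysis_is_opt_in(self):
        catalog = rule_catalog(include_provisional=True)
        assert len(catalog) == 12
        extra = [r for r in catalog if r.provisional]
        assert [r.id for r in extra] == ["benzoyl_hydrolysis"]

    def test_oxidative_defluorination_delta_mass(self, fluoro_poxizid):
        delta = rule_delta_mass("oxidative_defluorination", fluoro_poxizid)
        assert delta == pytest.approx(-1.9957, abs=5e-4)

    def test_dihydrodiol_delta_mass(self, mdmb):
        assert rule_delta_mass("dihydrodiol", mdmb) == pytest.approx(
            34.0055, abs=5e-4
        )

    def test_dealkylation_delta_is_parent_specific(self, adb, mdmb):
        assert rule_delta_mass("N_dealkylation", adb) == pytest.approx(
            -56.0626, abs=5e-4
        )
        assert rule_delta_mass("N_dealkylation", mdmb) == pytest.approx(
            -68.0626, abs=5e-4
        )

    def test_glucuronidation_is_terminal_phase_two(self):
        rule = RULES["glucuronidation"]
        assert rule.terminal and rule.phase == "II"


class TestApplyRule:
    def test_hydroxylation_of_adb_butinaca(self, adb):
        cand = apply_rule(root_candidate(adb), RULES["hydroxylation"])
        assert cand.mz == pytest.approx(347.2078, abs=1e-3)
        assert cand.composition == parse_formula("C18H26N4O3")

    def test_dihydrodiol_needs_an_alkene(self, adb, mdmb):
        assert apply_rule(root_candidate(adb), RULES["dihydrodiol"]) is None
        assert apply_rule(root_candidate(mdmb), RULES["dihydrodiol"]) is not None

    def test_glucuronidation_of_hydroxylated_adb(self, adb):
        hydroxylated = apply_rule(root_candidate(adb), RULES["hydroxylation"])
        conjugate = apply_rule(hydroxylated, RULES["glucuronidation"])
        assert conjugate.mz == pytest.approx(523.2399, abs=1e-3)

    def test_glucuronidation_needs_a_handle(self, adb):
        # no free hydroxyl/carboxyl on the parent itself
        assert apply_rule(root_candidate(adb), RULES["glucuronidation"]) is None

    def test_no_steps_after_a_terminal_conjugation(self, adb):
        hydroxylated = apply_rule(root_candidate(adb), RULES["hydroxylation"])
        conjugate = apply_rule(hydroxylated, RULES["glucuronidation"])
        assert apply_rule(conjugate, RULES["hydroxylation"]) is None

    def test_multiplicity_cap_enforced(self, adb):
        cand = root_candidate(adb)
        for _ in range(3):
            cand = apply_rule(cand, RULES["hydroxylation"])
        assert apply_rule(cand, RULES["hydroxylation"]) is None

    def test_dealkylation_after_defluorination_is_inapplicable(self, fluoro_poxizid):
        # the fluoropentyl loss formula no longer matches once F is gone
        defluorinated = apply_rule(
            root_candidate(fluoro_poxizid), RULES["oxidative_defluorination"]
        )
        assert apply_rule(defluorinated, RULES["N_dealkylation"]) is None


class TestEnumerate:
    def test_depth_one_adb_butinaca(self, adb):
        mzs = {round(c.mz, 4) for c in enumerate_metabolites(adb, max_depth=1)}
        assert {347.2078, 332.1969, 275.1503, 329.1972} <= mzs

    def test_empty_catalog_gives_no_candidates(self, adb):
        assert enumerate_metabolites(adb, catalog=[], max_depth=1) == []

    def test_defluorination_then_oxidation_to_acid(self, fluoro_poxizid):
        depth2 = enumerate_metabolites(fluoro_poxizid, max_depth=2)
        assert any(abs(c.mz - 366.1449) <= 1e-3 for c in depth2)

    def test_composition_conservation(self, mdmb):
        for cand in enumerate_metabolites(mdmb, max_depth=3):
            shift = Counter()
            for rule_id in cand.steps:
                rule = RULES[rule_id]
                delta = rule.delta
                if delta is None:
                    delta = {e: -n for e, n in mdmb.side_chain_loss.items()}
                shift.update(delta)
            expected = mdmb.composition.shift(dict(shift))
            assert cand.composition == expected

    @pytest.mark.parametrize(
        "name, forbidden",
        [
            ("ADB-BUTINACA", "oxidative_defluorination"),
            ("ADB-BUTINACA", "dihydrodiol"),
            ("BZO-POXIZID", "dihydrodiol"),
            ("BZO-HEXOXIZID", "oxidative_defluorination"),
        ],
    )
    def test_structural_gating(self, name, forbidden):
        parent = get_compound(name)
        for cand in enumerate_metabolites(parent, max_depth=4):
            assert forbidden not in cand.steps

    def test_at_most_one_glucuronide_and_always_last(self, mdmb):
        for cand in enumerate_metabolites(mdmb, max_depth=4):
            n_gluc = cand.steps.count("glucuronidation")
            assert n_gluc <= 1
            if n_gluc:
                assert cand.steps[-1] == "glucuronidation"

    def test_candidate_count_monotone_in_depth(self, fluoro_poxizid):
        counts = [
            len(enumerate_metabolites(fluoro_poxizid, max_depth=d))
            for d in (1, 2, 3, 4)
        ]
        assert counts == sorted(counts)

    def test_deduplicated_by_composition_and_multiset(self, adb):
        keys = [c.key for c in enumerate_metabolites(adb, max_depth=4)]
        assert len(keys) == len(set(keys))

    def test_caps_override(self, adb):
        capped = enumerate_metabolites(adb, max_depth=4, caps={"hydroxylation": 1})
        assert all(c.steps.count("hydroxylation") <= 1 for c in capped)

    def test_invalid_depth_rejected(self, adb):
        with pytest.raises(ValueError):
            enumerate_metabolites(adb, max_depth=0)


PRINTED_DEPTH1 = {
    # main-text metabolite m/z values reachable in one step
    "ADB-BUTINACA": [347.2078, 332.1969, 275.1503, 345.1921],
    "MDMB-4en-PINACA": [374.2074, 344.1969, 392.2180, 290.1499],
    "BZO-HEXOXIZID": [364.1656],
    "5F-BZO-POXIZID": [352.1656],
}


@pytest.mark.parametrize("name", sorted(PRINTED_DEPTH1))
def test_depth_one_reproduces_printed_values(name):
    parent = get_compound(name)
    mzs = [c.mz for c in enumerate_metabolites(parent, max_depth=1)]
    for printed in PRINTED_DEPTH1[name]:
        assert any(abs(mz - printed) <= 1e-3 for mz in mzs), printed


class TestRegistry:
    def test_six_parents_registered(self):
        names = set(load_compounds())
        assert len(names) == 6

    def test_inventory_consistent_with_composition(self):
        for compound in load_compounds().values():
            assert compound.has_fluorine == (compound.composition["F"] >= 1)
            compound.composition - compound.side_chain_loss  # must not raise

    @pytest.mark.parametrize(
        "alias", ["5-fluoro BZO-POXIZID", "5F BZO-POXIZID", "adb-butinaca"]
    )
    def test_alias_lookup(self, alias):
        assert get_compound(alias) is not None

    def test_unknown_parent_raises(self):
        with pytest.raises(KeyError):
            get_compound("JWH-018")

    def test_parent_mz_from_registry(self, mdmb):
        assert mdmb.mz == pytest.approx(358.2125, abs=1e-3)

    def test_side_chain_loss_mass_is_alkene_equivalent(self, hexoxizid):
        assert monoisotopic_mass(hexoxizid.side_chain_loss) == pytest.approx(
            84.0939, abs=5e-4
        )
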