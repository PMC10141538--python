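"""Composition arithmetic, accurate masses and formula fitting."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phasemet.chem import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    ElementalComposition,
    cation_mz,
    fit_composition,
    format_formula,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
    protonated_mz,
    rdbe,
)

compositions = st.builds(
    ElementalComposition,
    st.dictionaries(
        st.sampled_from(["C", "H", "N", "O", "F"]),
        st.integers(min_value=0, max_value=60),
        max_size=5,
    ),
)


class TestParseFormat:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("C18H26N4O2", {"C": 18, "H": 26, "N": 4, "O": 2}),
            ("C6H8O6", {"C": 6, "H": 8, "O": 6}),
            ("H2O", {"H": 2, "O": 1}),
            ("CH4", {"C": 1, "H": 4}),
        ],
    )
    def test_parse(self, text, expected):
        assert dict(parse_formula(text).items()) == expected

    @pytest.mark.parametrize("bad", ["", "   ", "C18H26N4O2X", "C-3", "12C", "Cx2"])
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    @given(compositions)
    def test_format_parse_round_trip(self, comp):
        if not comp:
            return
        assert parse_formula(format_formula(comp)) == comp

    def test_hill_order_puts_carbon_then_hydrogen_first(self):
        assert format_formula(parse_formula("O6H8C6")) == "C6H8O6"
        assert format_formula(parse_formula("OH2")) == "H2O"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition({"C": -1})

    def test_subtraction_underflow_is_an_error(self):
        with pytest.raises(ValueError):
            parse_formula("CH4") - parse_formula("C2")


class TestMasses:
    def test_proton_is_hydrogen_minus_electron(self):
        assert abs((MONOISOTOPIC_MASS["H"] - ELECTRON_MASS) - PROTON_MASS) < 1e-6

    @pytest.mark.parametrize(
        "formula, mass",
        [
            ("C6H8O6", 176.0321),  # glucuronide mass increment
            ("C4H8", 56.0626),  # N-butyl dealkylation loss
        ],
    )
    def test_known_neutral_masses(self, formula, mass):
        assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(
            mass, abs=5e-4
        )

    def test_empty_composition_has_zero_mass(self):
        assert monoisotopic_mass(ElementalComposition()) == 0.0

    @given(compositions, compositions)
    def test_mass_additivity(self, a, b):
        assert monoisotopic_mass(a + b) == pytest.approx(
            monoisotopic_mass(a) + monoisotopic_mass(b), abs=1e-9
        )

    @pytest.mark.parametrize(
        "formula, mz",
        [
            ("C18H26N4O2", 331.2129),  # ADB-BUTINACA
            ("C20H27N3O3", 358.2125),  # MDMB-4en-PINACA
            ("C21H23N3O2", 350.1863),  # BZO-HEXOXIZID
            ("C20H21N3O2", 336.1707),  # BZO-POXIZID
            ("C20H19N3O2", 334.1550),  # BZO-4en-POXIZID
            ("C20H20FN3O2", 354.1612),  # 5F-BZO-POXIZID
        ],
    )
    def test_protonated_mz_of_parents(self, formula, mz):
        assert protonated_mz(parse_formula(formula)) == pytest.approx(mz, abs=1e-3)

    @pytest.mark.parametrize(
        "formula, mz",
        [
            ("C7H5O", 105.0335),  # benzoyl oxonium
            ("C6H5", 77.0386),  # phenyl
            ("C5H9", 69.0699),  # pentenyl
        ],
    )
    def test_cation_mz_of_fragments(self, formula, mz):
        assert cation_mz(parse_formula(formula)) == pytest.approx(mz, abs=1e-3)


class TestPpmError:
    def test_identity_is_zero(self):
        assert ppm_error(331.2129, 331.2129) == 0.0

    def test_five_ppm_window_edge(self):
        assert ppm_error(331.21456, 331.2129) == pytest.approx(5.0, abs=0.05)

    def test_sign_preserved(self):
        assert ppm_error(99.999, 100.0) < 0

    @pytest.mark.parametrize("theoretical", [0.0, -10.0])
    def test_nonpositive_theoretical_rejected(self, theoretical):
        with pytest.raises(ValueError):
            ppm_error(100.0, theoretical)


def oracle_fit(target_mz, tol_ppm, bounds, ion_mode):
    """Independent nested-loop enumeration with its own mass table."""
    masses = {
        "C": 12.0,
        "H": 1.0078250319,
        "N": 14.0030740052,
        "O": 15.9949146221,
        "F": 18.9984032,
    }
    electron, proton = 0.0005485799, 1.0072764665
    elements = list(bounds)
    hits = set()
    for counts in itertools.product(*(range(bounds[e] + 1) for e in elements)):
        by_el = dict(zip(elements, counts))
        mass = sum(masses[e] * n for e, n in by_el.items())
        ring_double_bonds = (
            1.0
            + by_el.get("C", 0)
            - (by_el.get("H", 0) + by_el.get("F", 0)) / 2.0
            + by_el.get("N", 0) / 2.0
        )
        if ring_double_bonds < 0:
            continue
        half_integer = abs(ring_double_bonds - round(ring_double_bonds)) > 0.25
        if ion_mode == "protonated":
            if half_integer:
                continue
            theo = mass + proton
        else:
            theo = mass - electron if half_integer else mass
        if theo > 0 and abs((target_mz - theo) / theo * 1e6) <= tol_ppm:
            hits.add(frozenset((e, n) for e, n in by_el.items() if n))
    return hits


class TestFitComposition:
    def test_indazole_acylium_is_found(self):
        hits = fit_composition(
            145.0398, 5.0, {"C": 12, "H": 16, "N": 4, "O": 3}, ion_mode="cation"
        )
        assert parse_formula("C8H5N2O") in hits

    def test_neutral_loss_composition_found_without_electron_correction(self):
        hits = fit_composition(56.0626, 5.0, {"C": 6, "H": 14}, ion_mode="cation")
        assert parse_formula("C4H8") in hits

    def test_nothing_fits_in_tiny_bounds(self):
        assert fit_composition(1000.0, 0.0001, {"C": 2}, ion_mode="protonated") == []

    def test_results_sorted_by_absolute_ppm(self):
        hits = fit_composition(
            347.2080, 20.0, {"C": 20, "H": 30, "N": 5, "O": 5}, ion_mode="protonated"
        )
        errors = [
            abs(ppm_error(347.2080, protonated_mz(comp))) for comp in hits
        ]
        assert errors == sorted(errors)

    def test_rdbe_filter_excludes_impossible_formulas(self):
        # CH6 would need RDBE = -1
        hits = fit_composition(
            monoisotopic_mass(parse_formula("CH4")) + PROTON_MASS + 2 * 1.0078,
            50.0,
            {"C": 1, "H": 6},
            ion_mode="protonated",
        )
        assert parse_formula("CH6") not in hits

    @pytest.mark.parametrize("bad_call", [
        lambda: fit_composition(100.0, 0.0, {"C": 5}),
        lambda: fit_composition(100.0, 5.0, {}),
        lambda: fit_composition(100.0, 5.0, {"Xx": 3}),
        lambda: fit_composition(100.0, 5.0, {"C": 5}, ion_mode="anion"),
    ])
    def test_invalid_arguments_rejected(self, bad_call):
        with pytest.raises(ValueError):
            bad_call()

    @pytest.mark.parametrize("target, mode", [
        (145.0398, "cation"),
        (201.1025, "cation"),
        (331.2129, "protonated"),
        (176.0321, "protonated"),
    ])
    def test_agrees_with_exhaustive_oracle(self, target, mode):
        bounds = {"C": 10, "H": 20, "N": 4, "O": 4, "F": 1}
        ours = {
            frozenset(comp.items())
            for comp in fit_composition(target, 5.0, bounds, ion_mode=mode)
        }
        assert ours == oracle_fit(target, 5.0, bounds, mode)


def test_rdbe_values():
    assert rdbe(parse_formula("C6H6")) == pytest.approx(4.0)  # benzene
    assert rdbe(parse_formula("C8H5N2O")) == pytest.approx(7.5)  # acylium cation
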