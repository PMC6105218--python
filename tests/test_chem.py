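"""Formula arithmetic, ion masses, ppm convention and isotope simulation."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import isotope_pattern_oracle
from wwprofiler.chem import (Formula, HYDROGEN_MASS, IonSpecies, IsotopePeak,
                             IsotopePattern, PROTON_MASS, ion_mz,
                             monoisotopic_mass, ppm_error, rdbe,
                             simulate_isotope_pattern)
from wwprofiler._elements import ELEMENTS

formula_strategy = st.builds(
    Formula,
    st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S", "Cl"]),
                    st.integers(min_value=0, max_value=20), min_size=1))


class TestFormula:
    def test_parse_and_hill_order(self):
        f = Formula.parse("C15H12N2O")
        assert f["C"] == 15 and f["H"] == 12 and f["N"] == 2 and f["O"] == 1
        assert str(f) == "C15H12N2O"
        assert str(Formula.parse("H2O")) == "H2O"        # no carbon: alphabetical
        assert str(Formula.parse("C12H19Cl3O8")) == "C12H19Cl3O8"

    @pytest.mark.parametrize("bad", ["C-3H", "c6h6", "C6H6!", "1H2"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            Formula.parse(bad)

    @settings(max_examples=100, derandomize=True)
    @given(formula_strategy)
    def test_string_round_trip(self, f):
        assert Formula.parse(str(f)) == f


class TestMonoisotopicMass:
    def test_known_masses(self):
        assert monoisotopic_mass("C15H12N2O") == pytest.approx(236.09496, abs=1e-4)
        assert monoisotopic_mass("H2O") == pytest.approx(18.010565, abs=1e-5)
        assert monoisotopic_mass(Formula()) == 0.0

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            monoisotopic_mass(Formula({"Xx": 1}))

    @settings(max_examples=60, derandomize=True)
    @given(formula_strategy, formula_strategy)
    def test_additivity(self, f1, f2):
        assert monoisotopic_mass(f1 + f2) == pytest.approx(
            monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9)


class TestIonMz:
    @pytest.mark.parametrize("formula,adduct,convention,expected", [
        # proton-arithmetic reference values (printed at 4 decimals)
        ("C15H12N2O", "M+H", "proton", 237.1022),   # carbamazepine
        ("C8H9NO2", "M+H", "proton", 152.0706),     # paracetamol
        ("C8H8O3", "M-H", "proton", 151.0401),      # methyl paraben
        ("C9H10O3", "M-H", "proton", 165.0557),     # ethyl paraben
        # hydrogen-atom-arithmetic reference values (sweetener rows)
        ("C4H5NO4S", "M-H", "hydrogen", 161.9861),  # acesulfame
        ("C6H13NO3S", "M-H", "hydrogen", 178.0538), # cyclamate
        ("C12H19Cl3O8", "M-H", "hydrogen", 395.0067),  # sucralose
    ])
    def test_reference_values_4dp(self, formula, adduct, convention, expected):
        assert round(ion_mz(formula, adduct, convention), 4) == expected

    def test_unsupported_adduct(self):
        with pytest.raises(ValueError):
            ion_mz("C6H6", "M+Na")

    @settings(max_examples=60, derandomize=True)
    @given(formula_strategy)
    def test_adduct_difference_is_two_protons(self, f):
        assert ion_mz(f, "M+H") - ion_mz(f, "M-H") == pytest.approx(
            2 * PROTON_MASS, abs=1e-9)

    def test_convention_gap_is_electron_mass(self):
        gap = ion_mz("C6H6", "M+H", "hydrogen") - ion_mz("C6H6", "M+H", "proton")
        assert gap == pytest.approx(HYDROGEN_MASS - PROTON_MASS, abs=1e-9)

    def test_ion_species_consistency(self):
        with pytest.raises(ValueError):
            IonSpecies(Formula.parse("C6H6"), "M+H", "negative")
        ion = IonSpecies(Formula.parse("C15H12N2O"), "M+H", "positive")
        assert ion.mz == pytest.approx(237.1022, abs=1e-4)


class TestPpmError:
    @pytest.mark.parametrize("theo,exp,printed", [
        (178.0538, 178.0535, 1.68),     # cyclamate
        (237.1022, 237.1023, -0.42),    # carbamazepine
        (151.0401, 151.0404, -1.99),    # methyl paraben
    ])
    def test_sign_convention_reproduces_printed_errors(self, theo, exp, printed):
        assert round(ppm_error(theo, exp), 2) == printed

    def test_zero_for_identical(self):
        assert ppm_error(200.0, 200.0) == 0.0

    def test_rejects_nonpositive_theoretical(self):
        with pytest.raises(ValueError):
            ppm_error(0.0, 100.0)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(50, 2000), st.floats(-0.01, 0.01))
    def test_symmetry_about_theoretical(self, t, d):
        assert ppm_error(t, t + d) + ppm_error(t, t - d) == pytest.approx(0, abs=1e-9)


class TestRdbe:
    @pytest.mark.parametrize("formula,expected", [
        ("CH4", 0.0), ("C6H6", 4.0), ("C15H12N2O", 11.0),
        ("C12H19Cl3O8", 2.0), ("C8H10N4O2", 6.0),
    ])
    def test_known_values(self, formula, expected):
        assert rdbe(formula) == expected

    def test_unconfigured_valence(self):
        with pytest.raises(ValueError):
            rdbe(Formula({"He": 1}))


class TestIsotopePattern:
    def test_single_carbon(self):
        p = simulate_isotope_pattern("C", 2)
        ratio = 100 * ELEMENTS["C"][1].abundance / ELEMENTS["C"][0].abundance
        assert p.peaks[1].abundance_pct == pytest.approx(ratio, abs=1e-6)
        assert p.peaks[1].abundance_pct == pytest.approx(1.08, abs=0.01)

    def test_h2(self):
        p = simulate_isotope_pattern("H2", 2)
        assert p.peaks[1].abundance_pct == pytest.approx(0.023, abs=0.002)

    def test_pattern_invariants(self):
        p = simulate_isotope_pattern("C12H19Cl3O8", 4)
        assert p.peaks[0].shift_da == 0.0 and p.peaks[0].abundance_pct == 100.0
        shifts = p.shifts
        assert all(b > a for a, b in zip(shifts, shifts[1:]))
        # trichlorinated: M+2 dominated by 37Cl, almost as tall as M
        m2 = [pk for pk in p if round(pk.shift_da) == 2][0]
        assert m2.abundance_pct == pytest.approx(96, abs=3)
        assert m2.shift_da == pytest.approx(1.9971, abs=1e-3)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            IsotopePattern((IsotopePeak(0.0, 50.0),))
        with pytest.raises(ValueError):
            simulate_isotope_pattern("C6H6", 0)

    def test_matches_enumeration_oracle_for_all_suspects(self, suspects):
        """Convolution-based simulator vs exhaustive isotopologue
        enumeration, within 0.1% absolute abundance, for all 12 suspects."""
        for entry in suspects:
            sim = simulate_isotope_pattern(entry.formula, 4)
            expected = isotope_pattern_oracle(dict(entry.formula), 4)
            got = {round(pk.shift_da): pk.abundance_pct for pk in sim}
            for k in range(4):
                assert got.get(k, 0.0) == pytest.approx(expected[k], abs=0.1), \
                    f"{entry.name} M+{k}"

    @settings(max_examples=25, derandomize=True)
    @given(st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S", "Cl"]),
                           st.integers(1, 8), min_size=1, max_size=3))
    def test_matches_oracle_for_random_small_formulas(self, counts):
        sim = simulate_isotope_pattern(Formula(counts), 3)
        expected = isotope_pattern_oracle(counts, 3)
        got = {round(pk.shift_da): pk.abundance_pct for pk in sim}
        for k in range(3):
            assert got.get(k, 0.0) == pytest.approx(expected[k], abs=0.1)
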