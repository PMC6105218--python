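"""Formula enumeration, plausibility rules and the identification gates."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_formulas_oracle
from wwprofiler.chem import (Formula, IsotopePattern, IsotopePeak,
                             monoisotopic_mass, simulate_isotope_pattern)
from wwprofiler.extract import Feature, extract_features
from wwprofiler.identify import (IdentificationCriteria, element_bounds_for_mass,
                                 enumerate_formulas, golden_rules_filter,
                                 identification_score, identify, isotope_fit,
                                 passes_golden_rules)
from wwprofiler.simulate import generate_run


def feature_for(formula, polarity, mass_offset_da=0.0, pattern=None):
    mass = monoisotopic_mass(formula) + mass_offset_da
    if pattern is None:
        pattern = simulate_isotope_pattern(formula, 4)
    return Feature(mz=0.0, rt=0.0, abundance=1e5, polarity=polarity,
                   charge=1, isotope_pattern=pattern, neutral_mass=mass)


class TestEnumeration:
    def test_contains_known_formulas(self):
        bounds = {"C": 20, "H": 40, "N": 5, "O": 10}
        assert Formula.parse("C15H12N2O") in enumerate_formulas(
            236.09496, 2.0, bounds)
        assert Formula.parse("H2O") in enumerate_formulas(18.01056, 5.0, bounds)
        assert Formula.parse("C8H8O3") in enumerate_formulas(
            152.04734, 2.0, {"C": 20, "H": 40, "O": 10})

    def test_sorted_by_abs_ppm(self):
        res = enumerate_formulas(236.09496, 50.0, {"C": 20, "H": 40, "N": 5,
                                                   "O": 10})
        errs = [abs(monoisotopic_mass(f) - 236.09496) for f in res]
        assert errs == sorted(errs)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            enumerate_formulas(100.0, 0.0, {"C": 5})
        with pytest.raises(ValueError):
            enumerate_formulas(-5.0, 2.0, {"C": 5})

    @pytest.mark.parametrize("mass,tol", [
        (236.09496, 10.0), (152.04734, 20.0), (120.0, 40.0), (287.5, 15.0)])
    def test_complete_and_minimal_vs_bruteforce(self, mass, tol):
        """DFS enumeration returns exactly the brute-force set."""
        bounds = {"C": 20, "H": 40, "N": 5, "O": 10}
        fast = {str(f) for f in enumerate_formulas(mass, tol, bounds)}
        assert fast == enumerate_formulas_oracle(mass, tol, bounds)


class TestGoldenRules:
    def test_suspect_formulas_all_pass(self, suspects):
        verdicts = golden_rules_filter([e.formula for e in suspects])
        assert all(v is None for _, v in verdicts)

    def test_absurd_hydrogen_count_fails_hc_rule(self):
        (f, verdict), = golden_rules_filter([Formula({"C": 1, "H": 30})])
        assert verdict == "rule4_hc_ratio"

    def test_element_count_bound(self):
        crit = IdentificationCriteria(element_bounds={"C": 5, "H": 12})
        (_, verdict), = golden_rules_filter([Formula({"C": 6, "H": 6})], crit)
        assert verdict == "rule1_element_count"

    def test_negative_rdbe_rejected(self):
        # C2H8 would need RDBE = -1
        assert not passes_golden_rules(Formula({"C": 2, "H": 8}))

    def test_half_integer_rdbe_rejected(self):
        # odd-nitrogen-parity radical composition
        assert not passes_golden_rules(Formula({"C": 6, "H": 7, "N": 2}))

    def test_heteroatom_ratio_cap(self):
        (_, verdict), = golden_rules_filter([Formula({"C": 2, "H": 6, "O": 6})])
        assert verdict == "rule5_heteroatom_ratio"

    def test_nops_joint_cap(self):
        # all of N, O, P, S above 1 caps P at 4; P5 is individually legal
        f = Formula({"C": 25, "H": 53, "N": 2, "O": 2, "P": 5, "S": 2})
        (_, verdict), = golden_rules_filter([f])
        assert verdict == "rule6_nops"

    def test_mass_window_bounds_grow(self):
        assert element_bounds_for_mass(300)["C"] < element_bounds_for_mass(900)["C"]


class TestIsotopeFit:
    def test_identity_is_zero(self):
        f = Formula.parse("C15H12N2O")
        assert isotope_fit(f, simulate_isotope_pattern(f, 4)) == pytest.approx(0.0)

    def test_distorted_m2_deviation(self):
        """Trichlorinated pattern with M+2 observed at 91% instead of ~98%."""
        f = Formula.parse("C12H19Cl3O8")
        sim = simulate_isotope_pattern(f, 4)
        peaks = [IsotopePeak(p.shift_da, 91.0 if round(p.shift_da) == 2
                             else p.abundance_pct) for p in sim]
        dev = isotope_fit(f, IsotopePattern(tuple(peaks)))
        assert dev == pytest.approx(sim.peaks[2].abundance_pct - 91.0, abs=1e-9)

    def test_missing_observed_peak_counts_when_simulated_above_1pct(self):
        f = Formula.parse("C15H12N2O")   # M+1 ~ 16-17 %
        dev = isotope_fit(f, IsotopePattern((IsotopePeak(0.0, 100.0),)))
        m1 = simulate_isotope_pattern(f, 4).peaks[1].abundance_pct
        assert dev == pytest.approx(m1)
        assert dev > 15


class TestScore:
    def test_perfect_match(self):
        assert identification_score(0, 0, 0) == pytest.approx(100.0)

    def test_at_gate_thresholds(self):
        expected = 100 * (0.4 + 0.4 + 0.2) * math.exp(-1)
        assert identification_score(2, 5, 0.005) == pytest.approx(expected)
        assert identification_score(2, 5, 0.005) == pytest.approx(36.79, abs=0.01)

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 20), st.floats(0, 0.02),
           st.floats(0.01, 5))
    def test_monotone_decreasing_in_each_error(self, ppm, dev, sp, delta):
        base = identification_score(ppm, dev, sp)
        assert identification_score(ppm + delta, dev, sp) < base
        assert identification_score(ppm, dev + delta, sp) < base
        assert identification_score(ppm, dev, sp + delta * 1e-3) < base


class TestIdentify:
    def test_all_suspects_rank_one_on_clean_features(self, suspects):
        """Noise-free synthetic features recover every suspect formula as
        the single top-ranked accepted candidate."""
        for entry in suspects:
            feat = feature_for(entry.formula, entry.polarity)
            cands = identify(feat)
            assert cands, entry.name
            assert cands[0].formula == entry.formula, entry.name
            assert cands[0].score_pct > 98

    def test_three_ppm_mass_error_rejected(self):
        f = Formula.parse("C15H12N2O")
        mass = monoisotopic_mass(f)
        feat = feature_for(f, "positive", mass_offset_da=mass * 3e-6)
        assert all(c.formula != f for c in identify(feat))

    def test_distorted_isotope_cluster_rejected(self):
        f = Formula.parse("C15H12N2O")
        sim = simulate_isotope_pattern(f, 4)
        peaks = [IsotopePeak(p.shift_da, p.abundance_pct + (8.0 if i else 0.0))
                 for i, p in enumerate(sim)]
        feat = feature_for(f, "positive",
                           pattern=IsotopePattern(tuple(peaks)))
        assert all(c.formula != f for c in identify(feat))

    def test_gates_monotone_in_thresholds(self):
        """Relaxing any gate threshold never shrinks the accepted set."""
        f = Formula.parse("C8H9NO2")
        mass = monoisotopic_mass(f)
        sim = simulate_isotope_pattern(f, 4)
        peaks = [IsotopePeak(p.shift_da, p.abundance_pct * (1.03 if i else 1.0))
                 for i, p in enumerate(sim)]
        feat = feature_for(f, "positive", mass_offset_da=mass * 1.2e-6,
                           pattern=IsotopePattern(tuple(peaks)))
        prev: set[str] = set()
        for ppm_t, iso_t, score_t in [(1.5, 0.2, 99.9), (2.0, 5.0, 98.0),
                                      (3.0, 8.0, 90.0), (5.0, 15.0, 30.0)]:
            crit = IdentificationCriteria(max_ppm=ppm_t, max_iso_dev_pct=iso_t,
                                          min_score_pct=score_t)
            accepted = {str(c.formula) for c in identify(feat, crit)}
            assert prev <= accepted
            prev = accepted

    def test_feature_without_neutral_mass_rejected(self):
        feat = Feature(mz=300.0, rt=1.0, abundance=1e4, polarity="positive",
                       charge=2, neutral_mass=None)
        with pytest.raises(ValueError):
            identify(feat)

    def test_end_to_end_carbamazepine_from_synthetic_run(self, clean_config,
                                                         clean_ground_truth):
        run = generate_run(clean_config, "effluent", "A", "positive",
                          clean_ground_truth)
        feats = extract_features(run)
        target = min(feats, key=lambda f: abs(f.mz - 237.10224))
        cands = identify(target)
        assert cands[0].formula == Formula.parse("C15H12N2O")
        assert len(cands) == 1
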