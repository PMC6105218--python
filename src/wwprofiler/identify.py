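"""Molecular-formula assignment for extracted features.

The workflow is: exhaustive candidate enumeration over a bounded element
lattice, heuristic plausibility filtering ("golden rules": element-count
bounds per mass window, integer non-negative RDBE for even-electron
neutrals, H/C and heteroatom/C ratio limits, joint NOPS caps), then three
conjunctive acceptance gates —

* mass accuracy:   |error| <= 2 ppm (default),
* isotope fit:     max absolute isotope-ratio deviation <= 5 percentage
                   points against the simulated pattern,
* composite score: > 98 %.

The composite score is this package's own construction (vendor scores are
proprietary and undocumented): a weighted product-of-Gaussians in the three
error terms, 100 at zero error and monotonically decreasing in each.  It is
isolated in :func:`identification_score` so it can be swapped.

The TMS-adduct rule of the original heuristic rule set is GC-specific and
not applied; the isotope-pattern rule is realised by the isotope gate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chem import (Formula, IsotopePattern, IsotopePeak, monoisotopic_mass,
                   ppm_error, rdbe, simulate_isotope_pattern)
from ._elements import ELEMENTS

__all__ = ["IdentificationCriteria", "CandidateFormula",
           "element_bounds_for_mass", "enumerate_formulas",
           "golden_rules_filter", "passes_golden_rules",
           "isotope_fit", "identification_score", "identify"]

#: Element-count upper bounds by neutral-mass window (heuristic rule 1).
GOLDEN_ELEMENT_BOUNDS: list[tuple[float, dict[str, int]]] = [
    (500.0,  {"C": 29,  "H": 72,  "N": 10, "O": 18, "P": 4, "S": 7,  "Cl": 8}),
    (1000.0, {"C": 66,  "H": 126, "N": 25, "O": 27, "P": 6, "S": 8,  "Cl": 11}),
    (2000.0, {"C": 115, "H": 236, "N": 32, "O": 63, "P": 6, "S": 8,  "Cl": 11}),
    (3000.0, {"C": 162, "H": 208, "N": 48, "O": 78, "P": 6, "S": 9,  "Cl": 11}),
]


def element_bounds_for_mass(mass: float) -> dict[str, int]:
    """Default per-element count caps for a neutral mass (rule 1 table)."""
    for upper, bounds in GOLDEN_ELEMENT_BOUNDS:
        if mass < upper:
            return dict(bounds)
    return dict(GOLDEN_ELEMENT_BOUNDS[-1][1])


@dataclass
class IdentificationCriteria:
    """Thresholds of the identification gates and plausibility rules."""

    max_ppm: float = 2.0                 # mass-accuracy gate
    max_iso_dev_pct: float = 5.0         # isotope-ratio deviation gate
    min_score_pct: float = 98.0          # composite-score gate (strict >)
    hc_min: float = 0.2                  # H/C ratio window (rule 4)
    hc_max: float = 3.1
    ratio_caps: dict[str, float] = field(default_factory=lambda: {
        "N": 1.3, "O": 1.2, "P": 0.3, "S": 0.8, "Cl": 0.8})
    element_bounds: dict[str, int] | None = None   # None -> by mass window
    isotope_n_peaks: int = 4

    def __post_init__(self) -> None:
        if min(self.max_ppm, self.max_iso_dev_pct) <= 0:
            raise ValueError("ppm and isotope-deviation thresholds must be positive")
        if not 0 < self.min_score_pct <= 100:
            raise ValueError("min_score_pct must be in (0, 100]")


@dataclass
class CandidateFormula:
    """One formula hypothesis for a feature, with its gate verdicts."""

    formula: Formula
    neutral_mass: float          # theoretical monoisotopic mass
    ppm: float                   # signed mass error vs the measured mass
    rdbe: float
    iso_dev_pct: float | None = None
    score_pct: float | None = None
    accepted: bool = False
    failed_rule: str | None = None


def enumerate_formulas(mass: float, tol_ppm: float,
                       bounds: dict[str, int]) -> list[Formula]:
    """All formulas over the bounded element lattice whose monoisotopic mass
    lies within ``tol_ppm`` of ``mass``, sorted by |ppm error|.

    Exhaustive depth-first search over elements in decreasing atomic mass
    with window pruning, so completeness is guaranteed within the bounds.
    """
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if mass <= 0:
        raise ValueError("mass must be positive")
    lo = mass * (1 - tol_ppm * 1e-6)
    hi = mass * (1 + tol_ppm * 1e-6)
    elems = sorted(bounds, key=lambda s: ELEMENTS[s][0].mass, reverse=True)
    masses = [ELEMENTS[e][0].mass for e in elems]
    caps = [bounds[e] for e in elems]
    n = len(elems)
    # suffix_max[i] = largest mass attainable from elements i..n-1
    suffix_max = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + caps[i] * masses[i]

    results: list[Formula] = []
    counts = [0] * n

    def rec(i: int, acc: float) -> None:
        if i == n:
            if lo <= acc <= hi:
                results.append(Formula(dict(zip(elems, counts))))
            return
        em = masses[i]
        nmax = min(caps[i], int((hi - acc) / em))
        for c in range(nmax + 1):
            m2 = acc + c * em
            if m2 > hi:
                break
            if m2 + suffix_max[i + 1] < lo:
                continue
            counts[i] = c
            rec(i + 1, m2)
        counts[i] = 0

    rec(0, 0.0)
    results.sort(key=lambda f: (abs(monoisotopic_mass(f) - mass), str(f)))
    return results


def _check_rules(f: Formula, crit: IdentificationCriteria,
                 bounds: dict[str, int]) -> str | None:
    """Return the label of the first violated plausibility rule, else None."""
    for sym, count in f.items():
        if count > bounds.get(sym, 0):
            return "rule1_element_count"
    c = f["C"]
    if c > 0:
        hc = f["H"] / c
        if not crit.hc_min <= hc <= crit.hc_max:
            return "rule4_hc_ratio"
        for sym, cap in crit.ratio_caps.items():
            if f[sym] / c > cap:
                return "rule5_heteroatom_ratio"
    r = rdbe(f)
    if r < 0 or abs(r - round(r)) > 1e-9:
        return "rule2_rdbe"
    nn, oo, pp, ss = f["N"], f["O"], f["P"], f["S"]
    # joint NOPS plausibility caps (rule 6)
    if nn > 1 and oo > 1 and pp > 1 and ss > 1 and (nn > 10 or oo > 20 or pp > 4 or ss > 3):
        return "rule6_nops"
    if nn > 3 and oo > 3 and pp > 3 and (nn > 11 or oo > 22 or pp > 6):
        return "rule6_nops"
    if oo > 1 and pp > 1 and ss > 1 and (oo > 14 or pp > 3 or ss > 3):
        return "rule6_nops"
    if pp > 1 and ss > 1 and nn > 1 and (pp > 3 or ss > 3 or nn > 4):
        return "rule6_nops"
    if nn > 6 and oo > 6 and ss > 6 and (nn > 19 or oo > 14 or ss > 8):
        return "rule6_nops"
    return None


def golden_rules_filter(candidates: list[Formula],
                        criteria: IdentificationCriteria | None = None
                        ) -> list[tuple[Formula, str | None]]:
    """Apply the plausibility rules; each formula is paired with ``None`` if
    it passes or the label of the first failing rule."""
    crit = criteria or IdentificationCriteria()
    out = []
    for f in candidates:
        bounds = crit.element_bounds or element_bounds_for_mass(monoisotopic_mass(f))
        out.append((f, _check_rules(f, crit, bounds)))
    return out


def passes_golden_rules(f: Formula,
                        criteria: IdentificationCriteria | None = None) -> bool:
    return golden_rules_filter([f], criteria)[0][1] is None


def _bin_pattern(p: IsotopePattern) -> dict[int, tuple[float, float]]:
    return {int(round(pk.shift_da)): (pk.shift_da, pk.abundance_pct) for pk in p}


def isotope_fit(candidate: Formula, observed: IsotopePattern,
                n_peaks: int = 4) -> float:
    """Maximum absolute isotope-ratio deviation (percentage points of the
    monoisotopic peak) between the observed pattern and the pattern
    simulated for ``candidate``, over M+1 ... M+(n_peaks-1).

    A simulated peak above 1 % with no observed counterpart is compared
    against 0; an observed peak with no simulated counterpart counts at its
    full observed abundance.
    """
    if len(observed) < 1:
        raise ValueError("observed pattern must have at least one peak")
    sim = _bin_pattern(simulate_isotope_pattern(candidate, n_peaks))
    obs = _bin_pattern(observed)
    dev = 0.0
    for k in range(1, n_peaks):
        sim_ab = sim.get(k, (None, 0.0))[1]
        if k in obs:
            dev = max(dev, abs(obs[k][1] - sim_ab))
        elif sim_ab > 1.0:
            dev = max(dev, sim_ab)
    return dev


def _spacing_error(candidate: Formula, observed: IsotopePattern,
                   n_peaks: int) -> float:
    """Max |observed - simulated| exact-mass shift (Da) over shared bins."""
    sim = _bin_pattern(simulate_isotope_pattern(candidate, n_peaks))
    obs = _bin_pattern(observed)
    errs = [abs(obs[k][0] - sim[k][0]) for k in obs if k in sim and k > 0]
    return max(errs, default=0.0)


def identification_score(ppm: float, iso_dev_pct: float,
                         spacing_err_da: float = 0.0) -> float:
    """Composite identification score in percent.

    ``100 * (0.4*exp(-(ppm/2)^2) + 0.4*exp(-(dev/5)^2)
             + 0.2*exp(-(spacing/0.005)^2))`` — each term decays on the
    scale of its gate threshold; 100 at zero error.
    """
    return 100.0 * (0.4 * math.exp(-(ppm / 2.0) ** 2)
                    + 0.4 * math.exp(-(iso_dev_pct / 5.0) ** 2)
                    + 0.2 * math.exp(-(spacing_err_da / 0.005) ** 2))


def identify(feature, criteria: IdentificationCriteria | None = None
             ) -> list[CandidateFormula]:
    """Assign accepted molecular formulas to one extracted feature.

    Gates run cheapest-first (enumeration window -> plausibility rules ->
    ppm -> isotope fit -> score); because they are conjunctive the result is
    order-independent.  Returns accepted candidates sorted by score
    descending, ties broken by |ppm|.
    """
    crit = criteria or IdentificationCriteria()
    mass = getattr(feature, "neutral_mass", None)
    if mass is None:
        raise ValueError("feature has no neutral mass (charge != 1?)")
    observed = getattr(feature, "isotope_pattern", None)
    if observed is None or len(observed) == 0:
        observed = IsotopePattern((IsotopePeak(0.0, 100.0),))  # mono-only
    bounds = crit.element_bounds or element_bounds_for_mass(mass)
    accepted: list[CandidateFormula] = []
    for f, failed in golden_rules_filter(
            enumerate_formulas(mass, crit.max_ppm, bounds), crit):
        theo = monoisotopic_mass(f)
        cand = CandidateFormula(formula=f, neutral_mass=theo,
                                ppm=ppm_error(theo, mass), rdbe=rdbe(f),
                                failed_rule=failed)
        if failed is not None:
            continue
        if abs(cand.ppm) > crit.max_ppm:
            continue
        cand.iso_dev_pct = isotope_fit(f, observed, crit.isotope_n_peaks)
        if cand.iso_dev_pct > crit.max_iso_dev_pct:
            continue
        spacing = _spacing_error(f, observed, crit.isotope_n_peaks)
        cand.score_pct = identification_score(abs(cand.ppm), cand.iso_dev_pct,
                                              spacing)
        if cand.score_pct > crit.min_score_pct:
            cand.accepted = True
            accepted.append(cand)
    accepted.sort(key=lambda c: (-c.score_pct, abs(c.ppm), str(c.formula)))
    return accepted
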