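"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code path with the package: isotope patterns
come from exhaustive isotopologue enumeration with multinomial weights, and
formula search from plain nested iteration over the element lattice.
"""
from __future__ import annotations

import math
from itertools import product

from wwprofiler._elements import ELEMENTS


def _compositions(n: int, parts: int):
    """All tuples of `parts` non-negative integers summing to n."""
    if parts == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, parts - 1):
            yield (first,) + rest


def isotope_pattern_oracle(counts: dict[str, int], n_peaks: int) -> list[float]:
    """Relative abundances (% of the monoisotopic peak) of bins M..M+(n-1)
    by exhaustive enumeration of per-element isotopologue compositions."""
    per_element: list[dict[int, float]] = []
    for sym, n in counts.items():
        if n == 0:
            continue
        isotopes = ELEMENTS[sym]
        base_nominal = isotopes[0].nominal
        dist: dict[int, float] = {}
        for ks in _compositions(n, len(isotopes)):
            coef = math.factorial(n)
            prob = 1.0
            shift = 0
            for k, iso in zip(ks, isotopes):
                coef //= math.factorial(k)
                prob *= iso.abundance ** k
                shift += k * (iso.nominal - base_nominal)
            dist[shift] = dist.get(shift, 0.0) + coef * prob
        per_element.append(dist)
    total = {0: 1.0}
    for dist in per_element:
        merged: dict[int, float] = {}
        for s1, p1 in total.items():
            for s2, p2 in dist.items():
                merged[s1 + s2] = merged.get(s1 + s2, 0.0) + p1 * p2
        total = merged
    mono = total[0]
    return [100.0 * total.get(k, 0.0) / mono for k in range(n_peaks)]


def enumerate_formulas_oracle(mass: float, tol_ppm: float,
                              bounds: dict[str, int]) -> set[str]:
    """Formula strings within the ppm window by plain nested iteration."""
    elems = list(bounds)
    masses = [ELEMENTS[e][0].mass for e in elems]
    lo = mass * (1 - tol_ppm * 1e-6)
    hi = mass * (1 + tol_ppm * 1e-6)
    hits: set[str] = set()
    for combo in product(*(range(bounds[e] + 1) for e in elems)):
        m = sum(c * em for c, em in zip(combo, masses))
        if lo <= m <= hi:
            from wwprofiler.chem import Formula
            hits.add(str(Formula(dict(zip(elems, combo)))))
    return hits
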