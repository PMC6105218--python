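"""Formula arithmetic, accurate-mass calculations and isotope-pattern
simulation for small-molecule ESI-MS work.

All masses are monoisotopic and in daltons.  Singly charged ``[M+H]+`` /
``[M-H]-`` ions are the only adducts supported: these are the species an
electrospray Q-TOF monitors for the compound classes handled here
(sweeteners, pharmaceuticals, parabens and similar polar micropollutants).

Two ionization-mass conventions are exposed:

``proton``
    add/subtract the mass of a proton (1.00727646 Da) — physically correct
    for an ion that has gained/lost H+ and the package default.
``hydrogen``
    add/subtract the mass of a neutral hydrogen atom (1.00782503 Da) — the
    electron term is neglected.  Some published reference m/z values follow
    this arithmetic, so it is selectable for reproducing them.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from ._elements import (ELEMENTS, ELECTRON_MASS, HYDROGEN_MASS, PROTON_MASS,
                        VALENCES)

__all__ = [
    "Formula", "IonSpecies", "IsotopePeak", "IsotopePattern",
    "monoisotopic_mass", "ion_mz", "ppm_error", "rdbe",
    "simulate_isotope_pattern",
    "PROTON_MASS", "HYDROGEN_MASS", "ELECTRON_MASS",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(KeyError):
    """An element symbol has no entry in the isotope table."""


class Formula(Mapping[str, int]):
    """An elemental composition: element symbol -> non-negative count.

    Immutable, hashable, and round-trips through its Hill-notation string
    form (``Formula.parse(str(f)) == f``).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for sym, n in items.items():
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ValueError(f"count for {sym} must be a non-negative integer")
        self._counts: dict[str, int] = {s: int(n) for s, n in items.items() if n > 0}

    # -- Mapping protocol ---------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts.get(sym, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, sym: object) -> bool:
        return sym in self._counts

    # -- identity -----------------------------------------------------------
    def _key(self) -> tuple[tuple[str, int], ...]:
        return tuple(sorted(self._counts.items()))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Formula) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash(self._key())

    def __repr__(self) -> str:
        return f"Formula({str(self)!r})"

    # -- construction / formatting -------------------------------------------
    @classmethod
    def parse(cls, s: str) -> "Formula":
        """Parse a plain formula string such as ``"C15H12N2O"``."""
        s = s.strip()
        if not s:
            return cls()
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(s):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {s!r} at position {pos}")
            sym, digits = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
            pos = m.end()
        if pos != len(s):
            raise ValueError(f"cannot parse formula {s!r} at position {pos}")
        return cls(counts)

    def __str__(self) -> str:
        """Hill notation: C then H, remaining elements alphabetical; fully
        alphabetical when carbon is absent."""
        syms = sorted(self._counts)
        if "C" in self._counts:
            head = ["C"] + (["H"] if "H" in self._counts else [])
            syms = head + [s for s in syms if s not in ("C", "H")]
        parts = []
        for s in syms:
            n = self._counts[s]
            parts.append(s if n == 1 else f"{s}{n}")
        return "".join(parts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for s, n in other.items():
            merged[s] = merged.get(s, 0) + n
        return Formula(merged)

    @property
    def atom_count(self) -> int:
        return sum(self._counts.values())


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged ESI ion of a neutral molecule."""

    formula: Formula
    adduct: str            # "M+H" or "M-H"
    polarity: str          # "positive" or "negative"
    charge: int = 1

    def __post_init__(self) -> None:
        expected = {"M+H": "positive", "M-H": "negative"}
        if self.adduct not in expected:
            raise ValueError(f"unsupported adduct {self.adduct!r}")
        if expected[self.adduct] != self.polarity:
            raise ValueError(f"adduct {self.adduct} inconsistent with polarity {self.polarity}")
        if abs(self.charge) != 1:
            raise ValueError("only singly charged ions are supported")

    @property
    def mz(self) -> float:
        return ion_mz(self.formula, self.adduct)


@dataclass(frozen=True)
class IsotopePeak:
    shift_da: float        # exact-mass shift from the monoisotopic peak
    abundance_pct: float   # relative to the monoisotopic peak (= 100)


@dataclass(frozen=True)
class IsotopePattern:
    """Nominal-mass-aggregated isotope pattern: M, M+1, M+2, ...

    The first peak is the monoisotopic one (shift 0, abundance 100).  Each
    subsequent entry aggregates every isotopologue falling in that nominal
    bin; its shift is the abundance-weighted mean exact-mass shift.
    """

    peaks: tuple[IsotopePeak, ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("pattern needs at least one peak")
        p0 = self.peaks[0]
        if p0.shift_da != 0.0 or abs(p0.abundance_pct - 100.0) > 1e-9:
            raise ValueError("first peak must be (0, 100)")
        shifts = [p.shift_da for p in self.peaks]
        if any(b <= a for a, b in zip(shifts, shifts[1:])):
            raise ValueError("shifts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[IsotopePeak]:
        return iter(self.peaks)

    @property
    def abundances(self) -> list[float]:
        return [p.abundance_pct for p in self.peaks]

    @property
    def shifts(self) -> list[float]:
        return [p.shift_da for p in self.peaks]


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic (lightest-isotope) mass of a neutral formula, Da."""
    if isinstance(f, str):
        f = Formula.parse(f)
    total = 0.0
    for sym, n in f.items():
        try:
            isotopes = ELEMENTS[sym]
        except KeyError:
            raise UnknownElementError(sym) from None
        total += n * isotopes[0].mass
    return total


def ion_mz(f: Formula | str, adduct: str = "M+H", convention: str = "proton") -> float:
    """m/z of the singly charged ``[M+H]+`` or ``[M-H]-`` ion.

    ``convention`` selects the hydrogen-mass term (see module docstring).
    """
    if convention == "proton":
        dm = PROTON_MASS
    elif convention == "hydrogen":
        dm = HYDROGEN_MASS
    else:
        raise ValueError(f"unknown convention {convention!r}")
    m = monoisotopic_mass(f)
    if adduct == "M+H":
        return m + dm
    if adduct == "M-H":
        return m - dm
    raise ValueError(f"unsupported adduct {adduct!r}")


def ppm_error(theoretical: float, experimental: float) -> float:
    """Signed relative mass error in parts per million.

    Defined as ``(theoretical - experimental) / theoretical * 1e6``: a
    positive error means the measured m/z is *below* the theoretical one.
    """
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (theoretical - experimental) / theoretical * 1e6


def rdbe(f: Formula | str) -> float:
    """Ring-plus-double-bond equivalents: 1 + sum(n_i * (v_i - 2) / 2).

    Uses standard lowest valences (C=4, N=3, O=S=2, P=3, H=halogen=1).  An
    even-electron neutral molecule has integer RDBE >= 0; half-integer values
    flag radicals / impossible compositions.
    """
    if isinstance(f, str):
        f = Formula.parse(f)
    total = 1.0
    for sym, n in f.items():
        if sym not in VALENCES:
            raise ValueError(f"no valence configured for element {sym}")
        total += n * (VALENCES[sym] - 2) / 2.0
    return total


# --- isotope pattern simulation ---------------------------------------------
#
# Per element, the single-atom isotope distribution is expressed over integer
# nominal-mass shifts (0 = lightest isotope).  The n-atom distribution is the
# n-fold convolution, computed by binary exponentiation; element distributions
# are then convolved together.  Alongside each bin's probability we carry the
# probability-weighted total exact-mass shift, so the aggregated bin can
# report its mean exact-mass offset from the monoisotopic peak.

def _element_dist(sym: str, L: int) -> tuple[np.ndarray, np.ndarray]:
    try:
        isotopes = ELEMENTS[sym]
    except KeyError:
        raise UnknownElementError(sym) from None
    P = np.zeros(L)
    M = np.zeros(L)
    base = isotopes[0]
    for iso in isotopes:
        k = iso.nominal - base.nominal
        if k < L:
            P[k] += iso.abundance
            M[k] += iso.abundance * (iso.mass - base.mass)
    return P, M


def _conv(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray],
          L: int) -> tuple[np.ndarray, np.ndarray]:
    P = np.convolve(a[0], b[0])[:L]
    M = (np.convolve(a[1], b[0]) + np.convolve(a[0], b[1]))[:L]
    return P, M


def _power(dist: tuple[np.ndarray, np.ndarray], n: int,
           L: int) -> tuple[np.ndarray, np.ndarray]:
    unit_P = np.zeros(L)
    unit_P[0] = 1.0
    result = (unit_P, np.zeros(L))
    base = dist
    while n:
        if n & 1:
            result = _conv(result, base, L)
        n >>= 1
        if n:
            base = _conv(base, base, L)
    return result


def simulate_isotope_pattern(f: Formula | str, n_peaks: int = 4) -> IsotopePattern:
    """Aggregated isotope pattern of a neutral formula.

    Returns up to ``n_peaks`` nominal-mass bins (M, M+1, ...), abundances as
    percent of the monoisotopic peak.  Bins with probability < 1e-12 are
    dropped.  No fine structure: each bin is one peak at the mean exact-mass
    shift of its isotopologues.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if isinstance(f, str):
        f = Formula.parse(f)
    L = n_peaks
    P = np.zeros(L)
    P[0] = 1.0
    M = np.zeros(L)
    acc = (P, M)
    for sym, n in f.items():
        acc = _conv(acc, _power(_element_dist(sym, L), n, L), L)
    P, M = acc
    if P[0] <= 0:
        raise ValueError("monoisotopic probability vanished")
    peaks = [IsotopePeak(0.0, 100.0)]
    for k in range(1, L):
        if P[k] > 1e-12:
            peaks.append(IsotopePeak(float(M[k] / P[k]), float(100.0 * P[k] / P[0])))
    return IsotopePattern(tuple(peaks))
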