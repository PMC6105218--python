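"""Elemental isotope data (IUPAC 2013 atomic masses and representative
natural abundances) and standard valences.

Embedded as static data; nothing is fetched at run time.
"""
from __future__ import annotations

from typing import NamedTuple


class Isotope(NamedTuple):
    nominal: int        # nominal (integer) mass
    mass: float         # exact mass, Da
    abundance: float    # natural abundance, fraction


#: Per element: isotopes ordered by increasing nominal mass (first = lightest,
#: which for all supported elements is also the most abundant).
ELEMENTS: dict[str, list[Isotope]] = {
    "H": [Isotope(1, 1.00782503207, 0.999885),
          Isotope(2, 2.01410177812, 0.000115)],
    "C": [Isotope(12, 12.0, 0.9893),
          Isotope(13, 13.00335483507, 0.0107)],
    "N": [Isotope(14, 14.00307400443, 0.99636),
          Isotope(15, 15.00010889888, 0.00364)],
    "O": [Isotope(16, 15.99491461957, 0.99757),
          Isotope(17, 16.99913175650, 0.00038),
          Isotope(18, 17.99915961286, 0.00205)],
    "F": [Isotope(19, 18.99840316273, 1.0)],
    "Na": [Isotope(23, 22.98976928200, 1.0)],
    "P": [Isotope(31, 30.97376199842, 1.0)],
    "S": [Isotope(32, 31.97207117440, 0.9499),
          Isotope(33, 32.97145890980, 0.0075),
          Isotope(34, 33.96786700400, 0.0425),
          Isotope(36, 35.96708071000, 0.0001)],
    "Cl": [Isotope(35, 34.96885268200, 0.7576),
           Isotope(37, 36.96590260200, 0.2424)],
    "K": [Isotope(39, 38.96370648640, 0.932581),
          Isotope(40, 39.96399816600, 0.000117),
          Isotope(41, 40.96182525790, 0.067302)],
    "Br": [Isotope(79, 78.91833760000, 0.5069),
           Isotope(81, 80.91628970000, 0.4931)],
    "I": [Isotope(127, 126.90447190000, 1.0)],
}

#: Standard valences used for ring-plus-double-bond (RDBE) arithmetic.
VALENCES: dict[str, int] = {
    "C": 4, "H": 1, "N": 3, "O": 2, "P": 3, "S": 2,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "Na": 1, "K": 1,
}

PROTON_MASS = 1.00727646688      # mass of H+ (H atom minus electron), Da
HYDROGEN_MASS = 1.00782503207    # mass of the H atom, Da
ELECTRON_MASS = 0.00054857990    # Da
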