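"""Frozen physical constants for mass computations.

Monoisotopic atomic masses and isotope abundance tables are pinned here so
that every theoretical m/z produced by the package is bit-stable across
environments. Values follow the CODATA/IUPAC 2021 recommendations, truncated
to the precision relevant for high-resolution TOF work (< 1e-6 Da).
"""

from __future__ import annotations

#: Monoisotopic mass of the lightest stable isotope, in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
}

#: Mass of a proton (Da); [M-H]- means loss of H nucleus plus retention of
#: the electron, i.e. m/z = M - m_p for singly charged anions.
PROTON_MASS = 1.007276466812

#: Electron rest mass (Da).
ELECTRON_MASS = 0.000548579909

#: Isotope tables: per element, list of (mass shift in nucleons, relative
#: abundance). Abundances are normalised per element. Only isotopes with
#: abundance > 1e-5 are retained; this bounds envelope errors well below the
#: intensity thresholds used anywhere in the package.
ISOTOPE_ABUNDANCE: dict[str, list[tuple[int, float]]] = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
    "P": [(0, 1.0)],
    "Na": [(0, 1.0)],
}

#: Mass difference between consecutive isotopologue peaks used when placing
#: envelope peaks on an m/z axis (13C - 12C).
C13_C12_DELTA = 1.0033548378
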