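"""Physical constants for mass and isotope calculations.

Monoisotopic masses follow the CODATA/AME compilations; isotopic
abundances are the IUPAC 2013 representative values.  All charged-species
m/z values computed from these include the electron mass.
"""

from __future__ import annotations

# monoisotopic atomic masses, u
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.00054857991
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727645

#: mass difference between successive isotopologue peaks used when reading
#: an isotope envelope out of a survey scan (~13C - 12C)
ISOTOPE_SPACING = 1.0033548378

# (mass, abundance) per stable isotope, IUPAC 2013 representative values.
# Phosphorus is monoisotopic.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "H": ((1.00782503207, 0.999885), (2.0141017778, 0.000115)),
    "N": ((14.0030740048, 0.99636), (15.0001088982, 0.00364)),
    "O": (
        (15.9949146196, 0.99757),
        (16.9991317, 0.00038),
        (17.999161, 0.00205),
    ),
    "P": ((30.97376163, 1.0),),
    "S": (
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
    ),
}

# masses of small neutrals that appear as losses in negative-mode CID
MASS_H2O = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]  # 18.010565
MASS_H2O2 = 2 * MONOISOTOPIC_MASS["H"] + 2 * MONOISOTOPIC_MASS["O"]  # 34.005480
MASS_CO2 = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["O"]  # 43.989830
MASS_HCOOH = (
    MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"] + 2 * MONOISOTOPIC_MASS["O"]
)  # 46.005480
MASS_CH3 = MONOISOTOPIC_MASS["C"] + 3 * MONOISOTOPIC_MASS["H"]
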