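"""Versioned physical-constant tables shared by the property calculators.

All residue masses are for the amino-acid *residue* (monomer minus water).
Monoisotopic values derive from CODATA/IUPAC 2021 atomic masses; average
values from IUPAC 2021 standard atomic weights. Version tags let callers
pin a table if values are ever revised.
"""

from __future__ import annotations

CONSTANTS_VERSION = "2021.1"

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Atomic monoisotopic masses (Da)
MONO_H = 1.0078250319
MONO_C = 12.0
MONO_N = 14.0030740052
MONO_O = 15.9949146221
MONO_S = 31.97207069

PROTON_MASS = 1.00727646  # Da; m/z arithmetic uses the proton, not H

WATER_MONO = 2 * MONO_H + MONO_O          # 18.0105646859

# Standard atomic weights (IUPAC 2021, abridged)
AVG_H = 1.008
AVG_C = 12.011
AVG_N = 14.007
AVG_O = 15.999
AVG_S = 32.06

HYDROGEN_AVG = AVG_H
WATER_AVG = 2 * AVG_H + AVG_O             # 18.015

# Residue elemental compositions (C, H, N, O, S)
RESIDUE_COMPOSITION: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}


def _mono_from_composition(c: int, h: int, n: int, o: int, s: int) -> float:
    return c * MONO_C + h * MONO_H + n * MONO_N + o * MONO_O + s * MONO_S


RESIDUE_MONO_MASS: dict[str, float] = {
    aa: _mono_from_composition(*comp) for aa, comp in RESIDUE_COMPOSITION.items()
}

def _avg_from_composition(c: int, h: int, n: int, o: int, s: int) -> float:
    return c * AVG_C + h * AVG_H + n * AVG_N + o * AVG_O + s * AVG_S


# Average residue masses (Da), standard-atomic-weight sums
RESIDUE_AVG_MASS: dict[str, float] = {
    aa: _avg_from_composition(*comp) for aa, comp in RESIDUE_COMPOSITION.items()
}

# pKa sets. Side-chain keys are residue letters; termini keyed explicitly.
PKA_TABLES: dict[str, dict[str, float]] = {
    "emboss": {
        "n_term": 8.6,
        "c_term": 3.6,
        "K": 10.8,
        "R": 12.5,
        "H": 6.5,
        "D": 3.9,
        "E": 4.1,
        "C": 8.5,
        "Y": 10.1,
    },
}
DEFAULT_PKA_TABLE = "emboss"

BASIC_SIDECHAINS = ("K", "R", "H")
ACIDIC_SIDECHAINS = ("D", "E", "Y")  # C handled separately (disulfide-aware)

# Hydrophobicity scales (per-residue).
HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "kyte_doolittle": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
}
DEFAULT_HYDROPHOBICITY_SCALE = "kyte_doolittle"

# Residues outside the standard 20, for targeted error messages.
NONSTANDARD_RESIDUE_NAMES = {
    "B": "Asx (Asn/Asp ambiguity)",
    "J": "Xle (Leu/Ile ambiguity)",
    "O": "pyrrolysine",
    "U": "selenocysteine",
    "X": "unknown residue",
    "Z": "Glx (Gln/Glu ambiguity)",
}
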