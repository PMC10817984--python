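"""Amino-acid bookkeeping tables.

Elemental compositions are stored per *residue* (the free amino acid minus
one water, i.e. the repeating unit of a peptide chain). Adding one H2O to a
summed chain recovers the composition of the free peptide. The free
amino-acid compositions used to derive the table are unit-tested against
standard formulas (glycine C2H5NO2, alanine C3H7NO2, ...).
"""

from __future__ import annotations

from collections.abc import Mapping

# Single-letter codes of the 20 standard amino acids, alphabetical.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

# Symbols that may appear in protein sequences but carry no defined
# composition here: ambiguity codes, rare residues, stop.
NONSTANDARD_SYMBOLS: frozenset[str] = frozenset("XBZUJO*")

# Residue elemental composition (C, H, N, O, S) = free amino acid - H2O.
RESIDUE_COMPOSITION: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 5, 1, 1, 0),    # Ala
    "C": (3, 5, 1, 1, 1),    # Cys
    "D": (4, 5, 1, 3, 0),    # Asp
    "E": (5, 7, 1, 3, 0),    # Glu
    "F": (9, 9, 1, 1, 0),    # Phe
    "G": (2, 3, 1, 1, 0),    # Gly
    "H": (6, 7, 3, 1, 0),    # His
    "I": (6, 11, 1, 1, 0),   # Ile
    "K": (6, 12, 2, 1, 0),   # Lys
    "L": (6, 11, 1, 1, 0),   # Leu
    "M": (5, 9, 1, 1, 1),    # Met
    "N": (4, 6, 2, 2, 0),    # Asn
    "P": (5, 7, 1, 1, 0),    # Pro
    "Q": (5, 8, 2, 2, 0),    # Gln
    "R": (6, 12, 4, 1, 0),   # Arg
    "S": (3, 5, 1, 2, 0),    # Ser
    "T": (4, 7, 1, 2, 0),    # Thr
    "V": (5, 9, 1, 1, 0),    # Val
    "W": (11, 10, 2, 1, 0),  # Trp
    "Y": (9, 9, 1, 2, 0),    # Tyr
}

WATER: tuple[int, int, int, int, int] = (0, 2, 0, 1, 0)

# Conventional atomic weights, g/mol.
ATOMIC_WEIGHT: dict[str, float] = {"C": 12.011, "H": 1.008, "O": 15.999}

# Residues entering the thermophily proxy: Ile, Val, Tyr, Trp, Arg, Glu, Leu.
IVYWREL: frozenset[str] = frozenset("IVYWREL")

# Typical bacterial proteome residue frequencies (order of STANDARD_RESIDUES),
# used as the default composition for simulated communities. Normalised on use.
TYPICAL_PROTEOME_FREQS: dict[str, float] = {
    "A": 0.089, "C": 0.012, "D": 0.054, "E": 0.061, "F": 0.039,
    "G": 0.074, "H": 0.021, "I": 0.059, "K": 0.053, "L": 0.099,
    "M": 0.023, "N": 0.041, "P": 0.044, "Q": 0.038, "R": 0.051,
    "S": 0.061, "T": 0.054, "V": 0.071, "W": 0.013, "Y": 0.031,
}


def free_amino_acid_composition(residue: str) -> tuple[int, int, int, int, int]:
    """Composition of the free amino acid (residue + one water)."""
    c, h, n, o, s = RESIDUE_COMPOSITION[residue]
    return (c, h + 2, n, o + 1, s)
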