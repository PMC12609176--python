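"""Residue-level lookup tables used by the node featurizer.

All scales are standard published tables, compiled once and versioned here:
Kyte-Doolittle hydropathy, Grantham polarity, side-chain pKa values from
common biochemistry references, Bondi van der Waals radii, monoisotopic
residue masses.  The featurizer z-scores the six physicochemical properties
across the 20 standard residues at import time, so the packaged numbers stay
on their original published scales.
"""

from __future__ import annotations

import numpy as np

TABLE_VERSION = "1.0"

# one-hot order: 20 standard residues alphabetically by one-letter code, then X
AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

# active-site category labels; index 0 is the non-site class
CLASS_NAMES = ("None", "CRI", "SCI", "PI", "PTCR", "IA", "SSA")
# cross-entropy class weights, indexed like CLASS_NAMES
CLASS_WEIGHTS = (0.01, 1.0, 0.7, 1.0, 0.5, 2.5, 2.0)

# Kyte-Doolittle hydropathy index
HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Grantham (1974) polarity
POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

# formal side-chain charge at pH 7 (His treated neutral, pKa ~6)
SIDECHAIN_CHARGE = {
    "D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0,
}

# side-chain ionizable-group pKa; residues without one carry 0
SIDECHAIN_PKA = {
    "D": 3.65, "E": 4.25, "H": 6.0, "C": 8.3, "Y": 10.07,
    "K": 10.53, "R": 12.48,
}

# van der Waals volume, A^3
VDW_VOLUME = {
    "A": 67.0, "R": 148.0, "N": 96.0, "D": 91.0, "C": 86.0, "Q": 114.0,
    "E": 109.0, "G": 48.0, "H": 118.0, "I": 124.0, "L": 124.0, "K": 135.0,
    "M": 124.0, "F": 135.0, "P": 90.0, "S": 73.0, "T": 93.0, "W": 163.0,
    "Y": 141.0, "V": 105.0,
}

# monoisotopic residue (chain-internal) mass, Da
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# side-chain hydrogen-bonding capability: donor H count + acceptor heavy atoms
HBOND_CAPABILITY = {
    "S": 2, "T": 2, "C": 1, "Y": 2, "N": 3, "Q": 3, "D": 2, "E": 2,
    "K": 3, "R": 5, "H": 2, "W": 1, "M": 1,
}

# aromatic-ring side chains
AROMATIC = frozenset("FWYH")

# element -> (atomic mass Da, Bondi vdW radius A)
ELEMENTS = {
    "H": (1.008, 1.20),
    "C": (12.011, 1.70),
    "N": (14.007, 1.55),
    "O": (15.999, 1.52),
    "S": (32.06, 1.80),
    "SE": (78.97, 1.90),
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})

# chi-angle defining atom quadruples, chi1..chi5 where present
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ"),
            ("CD", "NE", "CZ", "NH1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}


def _zscore_table(table: dict[str, float]) -> dict[str, float]:
    vals = np.array([table.get(a, 0.0) for a in AA_ORDER[:20]])
    mu, sd = vals.mean(), vals.std(ddof=0)
    return {a: (table.get(a, 0.0) - mu) / sd for a in AA_ORDER[:20]}


def physchem_zscored() -> dict[str, np.ndarray]:
    """Per-residue 6-vector of z-scored physicochemical properties.

    Order: hydrophobicity, polarity, charge, pKa, volume, mass.
    'X' (unknown) maps to the zero vector.
    """
    charge = {a: SIDECHAIN_CHARGE.get(a, 0.0) for a in AA_ORDER[:20]}
    pka = {a: SIDECHAIN_PKA.get(a, 0.0) for a in AA_ORDER[:20]}
    cols = [_zscore_table(t) for t in
            (HYDROPHOBICITY, POLARITY, charge, pka, VDW_VOLUME, RESIDUE_MASS)]
    out = {a: np.array([c[a] for c in cols]) for a in AA_ORDER[:20]}
    out["X"] = np.zeros(6)
    return out


PHYSCHEM = physchem_zscored()
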