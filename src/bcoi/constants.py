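"""Physical constants and model-compound parameters.

The temperature is fixed at 300 K so that a coupling of two pKa units,
2·ln(10)·R·T, equals 11.49 kJ/mol — the magnitude used to define strong
charge–charge coupling throughout the package.
"""

import math

#: Gas constant, kJ/(mol·K).
R_KJ = 8.31446e-3

#: Working temperature, K.
T_DEFAULT = 300.0

#: ln(10)·R·T at 300 K — converts pKa units to kJ/mol (≈ 5.744).
LN10_RT = math.log(10.0) * R_KJ * T_DEFAULT

#: Coulomb constant in kJ·Å/mol (e²/(4πε₀) in these units).
KE_KJ_A = 1389.35

#: Coupling threshold marking strong pairwise interaction, kJ/mol (ΔpKa ≥ 2).
COUPLING_THRESHOLD = 11.5

#: Model-compound (solution) pKa per titratable group type.
MODEL_PKA = {
    "ASP": 4.0,
    "GLU": 4.4,
    "LYS": 10.4,
    "ARG": 12.0,
    "HIS": 6.3,
    "CYS": 8.7,
    "TYR": 9.6,
    "NTERM": 8.0,
    "CTERM": 3.6,
}

#: Ionisation sign: +1 for bases (charged when protonated), −1 for acids.
GAMMA = {
    "ASP": -1,
    "GLU": -1,
    "CYS": -1,
    "TYR": -1,
    "CTERM": -1,
    "LYS": +1,
    "ARG": +1,
    "HIS": +1,
    "NTERM": +1,
}

#: Side-chain / terminal atoms carrying the titratable charge.  Burial is
#: assessed on these atoms only, so that low SASA reflects charge desolvation
#: rather than backbone packing.
MOIETY_ATOMS = {
    "ASP": ("CG", "OD1", "OD2"),
    "GLU": ("CD", "OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ", "NE", "NH1", "NH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "CYS": ("SG",),
    "TYR": ("OH",),
    "NTERM": ("N",),
    "CTERM": ("C", "O", "OXT"),
}

#: Group types assessed for buried charge of interest (BCOI).
ASSESSED_GROUPS = frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"})

#: van der Waals radii by element, Å.
ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70

#: Water-probe radius, Å.
PROBE_RADIUS = 1.4

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: One-letter code → titratable side-chain group type.
SIDECHAIN_GROUP = {"D": "ASP", "E": "GLU", "K": "LYS", "R": "ARG",
                   "H": "HIS", "C": "CYS", "Y": "TYR"}
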