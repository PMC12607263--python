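"""Element and residue parameter tables used across the package.

All radii are in Angstroms. Sources are cited next to each table; values are
transcribed from the primary literature and are the ones in common use by
structure-analysis software.
"""

from __future__ import annotations

# van der Waals radii (Bondi 1964, J. Phys. Chem. 68:441; H from Rowland &
# Taylor 1996). Used for Shrake-Rupley SASA.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "FE": 2.00,
}

#: Radius assigned to elements missing from :data:`VDW_RADII` (carbon-like).
DEFAULT_VDW_RADIUS = 1.70

# Single-bond covalent radii (Cordero et al. 2008, Dalton Trans. 2832).
# Used for distance-based bond perception.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "P": 1.07,
    "S": 1.05,
    "CL": 1.02,
    "BR": 1.20,
    "I": 1.39,
    "SE": 1.20,
}

DEFAULT_COVALENT_RADIUS = 0.77

# Gasteiger-Marsili PEOE electronegativity coefficients (a, b, c) per
# element/hybridization class (Gasteiger & Marsili 1980, Tetrahedron
# 36:3219, Table 1).  chi(q) = a + b*q + c*q^2; the cation
# electronegativity chi(+1) = a + b + c normalizes the charge transferred
# out of the donor atom, except hydrogen where the original work fixes it
# at 20.02.
GASTEIGER_PARAMS: dict[str, tuple[float, float, float]] = {
    "H": (7.17, 6.24, -0.56),
    "C.3": (7.98, 9.18, 1.88),
    "C.2": (8.79, 9.32, 1.51),
    "C.1": (10.39, 9.45, 0.73),
    "N.3": (11.54, 10.82, 1.36),
    "N.2": (12.87, 11.15, 0.85),
    "N.1": (15.68, 11.70, -0.27),
    "O.3": (14.18, 12.92, 1.39),
    "O.2": (17.07, 13.79, 0.47),
    "F": (14.66, 13.85, 2.31),
    "CL": (11.00, 9.69, 1.35),
    "BR": (10.08, 8.47, 1.16),
    "I": (9.90, 7.96, 0.96),
    "S.3": (10.14, 9.13, 1.38),
}

HYDROGEN_CATION_CHI = 20.02

# Model-compound pKa values for titratable groups (standard textbook
# values, e.g. Thurlkill et al. 2006 Protein Sci. 15:1214 and the PROPKA
# model-pKa table).
MODEL_PKA: dict[str, float] = {
    "ASP": 3.80,
    "GLU": 4.50,
    "HIS": 6.50,
    "CYS": 9.00,
    "TYR": 10.00,
    "LYS": 10.50,
    "ARG": 12.50,
    "N-term": 8.00,
    "C-term": 3.20,
}

#: Side-chain groups that release a proton on deprotonation of an acid
#: (burial raises pKa) versus bases (burial lowers pKa).
ACIDIC_GROUPS = frozenset({"ASP", "GLU", "CYS", "TYR", "C-term"})
BASIC_GROUPS = frozenset({"HIS", "LYS", "ARG", "N-term"})

# Theoretical maximum accessible surface area per residue type in an
# extended Gly-X-Gly context (Tien et al. 2013, PLoS ONE 8:e80635,
# "theoretical" column), in Angstrom^2.  Used to convert absolute SASA to
# relative exposure.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

#: Fallback maximum SASA for non-standard residues (median of the table).
DEFAULT_MAX_SASA = 201.0

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
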