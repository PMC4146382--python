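"""Physical constants and lookup tables shared across the package.

All coordinates are carried in Angstrom and all energies in kcal/mol;
conversions to nm happen only in reporting code.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_MOL_K = 0.0019872

#: Simulation/analysis temperature in K.
DEFAULT_TEMPERATURE_K = 300.0

#: k_B T at 300 K, kcal/mol.
KT_300 = KB_KCAL_MOL_K * DEFAULT_TEMPERATURE_K

# Bondi van der Waals radii (A); fallback used for anything not listed.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "CL": 1.75,
    "K": 2.75,
    "F": 1.47,
    "NA": 2.27,
}
DEFAULT_VDW_RADIUS = 1.70

# Residue names recognised as ions, per force-field dialect.
CHLORIDE_RESNAMES = ("CLA", "CL", "CL-")
POTASSIUM_RESNAMES = ("POT", "K", "K+")

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
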