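"""Published constant tables for protein physicochemical indices.

Sources: average residue masses and ionizable-group pK values as used by
the ExPASy ProtParam service (Bjellqvist pK set); Kyte & Doolittle (1982)
hydropathy scale; Guruprasad, Reddy & Pandit (1990) dipeptide instability
weight values (DIWV); Ikai (1980) aliphatic-index coefficients.
"""

WATER_MASS = 18.01524  # Da, added once per chain

# Average (not monoisotopic) residue masses, Da.
RESIDUE_MASS = {
    "A": 71.0788,
    "C": 103.1388,
    "D": 115.0886,
    "E": 129.1155,
    "F": 147.1766,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "K": 128.1741,
    "L": 113.1594,
    "M": 131.1926,
    "N": 114.1038,
    "P": 97.1167,
    "Q": 128.1307,
    "R": 156.1875,
    "S": 87.0782,
    "T": 101.1051,
    "V": 99.1326,
    "W": 186.2132,
    "Y": 163.176,
}

# Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8,
    "C": 2.5,
    "D": -3.5,
    "E": -3.5,
    "F": 2.8,
    "G": -0.4,
    "H": -3.2,
    "I": 4.5,
    "K": -3.9,
    "L": 3.8,
    "M": 1.9,
    "N": -3.5,
    "P": -1.6,
    "Q": -3.5,
    "R": -4.5,
    "S": -0.8,
    "T": -0.7,
    "V": 4.2,
    "W": -0.9,
    "Y": -1.3,
}

# Bjellqvist pK values (ProtParam convention; termini without
# residue-specific adjustment).
PK_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PK_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

# Dipeptide instability weight values, DIWV[first][second].
DIWV = {
    "A": {"A": 1.0, "C": 44.94, "D": -7.49, "E": 1.0, "F": 1.0, "G": 1.0, "H": -7.49, "I": 1.0, "K": 1.0, "L": 1.0, "M": 1.0, "N": 1.0, "P": 20.26, "Q": 1.0, "R": 1.0, "S": 1.0, "T": 1.0, "V": 1.0, "W": 1.0, "Y": 1.0},
    "C": {"A": 1.0, "C": 1.0, "D": 20.26, "E": 1.0, "F": 1.0, "G": 1.0, "H": 33.6, "I": 1.0, "K": 1.0, "L": 20.26, "M": 33.6, "N": 1.0, "P": 20.26, "Q": -6.54, "R": 1.0, "S": 1.0, "T": 33.6, "V": -6.54, "W": 24.68, "Y": 1.0},
    "D": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 1.0, "F": -6.54, "G": 1.0, "H": 1.0, "I": 1.0, "K": -7.49, "L": 1.0, "M": 1.0, "N": 1.0, "P": 1.0, "Q": 1.0, "R": -6.54, "S": 20.26, "T": -14.03, "V": 1.0, "W": 1.0, "Y": 1.0},
    "E": {"A": 1.0, "C": 44.94, "D": 20.26, "E": 33.6, "F": 1.0, "G": 1.0, "H": -6.54, "I": 20.26, "K": 1.0, "L": 1.0, "M": 1.0, "N": 1.0, "P": 20.26, "Q": 20.26, "R": 1.0, "S": 20.26, "T": 1.0, "V": 1.0, "W": -14.03, "Y": 1.0},
    "F": {"A": 1.0, "C": 1.0, "D": 13.34, "E": 1.0, "F": 1.0, "G": 1.0, "H": 1.0, "I": 1.0, "K": -14.03, "L": 1.0, "M": 1.0, "N": 1.0, "P": 20.26, "Q": 1.0, "R": 1.0, "S": 1.0, "T": 1.0, "V": 1.0, "W": 1.0, "Y": 33.601},
    "G": {"A": -7.49, "C": 1.0, "D": 1.0, "E": -6.54, "F": 1.0, "G": 13.34, "H": 1.0, "I": -7.49, "K": -7.49, "L": 1.0, "M": 1.0, "N": -7.49, "P": 1.0, "Q": 1.0, "R": 1.0, "S": 1.0, "T": -7.49, "V": 1.0, "W": 13.34, "Y": -7.49},
    "H": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 1.0, "F": -9.37, "G": -9.37, "H": 1.0, "I": 44.94, "K": 24.68, "L": 1.0, "M": 1.0, "N": 24.68, "P": -1.88, "Q": 1.0, "R": 1.0, "S": 1.0, "T": -6.54, "V": 1.0, "W": -1.88, "Y": 44.94},
    "I": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 44.94, "F": 1.0, "G": 1.0, "H": 13.34, "I": 1.0, "K": -7.49, "L": 20.26, "M": 1.0, "N": 1.0, "P": -1.88, "Q": 1.0, "R": 1.0, "S": 1.0, "T": 1.0, "V": -7.49, "W": 1.0, "Y": 1.0},
    "K": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 1.0, "F": 1.0, "G": -7.49, "H": 1.0, "I": -7.49, "K": 1.0, "L": -7.49, "M": 33.6, "N": 1.0, "P": -6.54, "Q": 24.64, "R": 33.6, "S": 1.0, "T": 1.0, "V": -7.49, "W": 1.0, "Y": 1.0},
    "L": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 1.0, "F": 1.0, "G": 1.0, "H": 1.0, "I": 1.0, "K": -7.49, "L": 1.0, "M": 1.0, "N": 1.0, "P": 20.26, "Q": 33.6, "R": 20.26, "S": 1.0, "T": 1.0, "V": 1.0, "W": 24.68, "Y": 1.0},
    "M": {"A": 13.34, "C": 1.0, "D": 1.0, "E": 1.0, "F": 1.0, "G": 1.0, "H": 58.28, "I": 1.0, "K": 1.0, "L": 1.0, "M": -1.88, "N": 1.0, "P": 44.94, "Q": -6.54, "R": -6.54, "S": 44.94, "T": -1.88, "V": 1.0, "W": 1.0, "Y": 24.68},
    "N": {"A": 1.0, "C": -1.88, "D": 1.0, "E": 1.0, "F": -14.03, "G": -14.03, "H": 1.0, "I": 44.94, "K": 24.68, "L": 1.0, "M": 1.0, "N": 1.0, "P": -1.88, "Q": -6.54, "R": 1.0, "S": 1.0, "T": -7.49, "V": 1.0, "W": -9.37, "Y": 1.0},
    "P": {"A": 20.26, "C": -6.54, "D": -6.54, "E": 18.38, "F": 20.26, "G": 1.0, "H": 1.0, "I": 1.0, "K": 1.0, "L": 1.0, "M": -6.54, "N": 1.0, "P": 20.26, "Q": 20.26, "R": -6.54, "S": 20.26, "T": 1.0, "V": 20.26, "W": -1.88, "Y": 1.0},
    "Q": {"A": 1.0, "C": -6.54, "D": 20.26, "E": 20.26, "F": -6.54, "G": 1.0, "H": 1.0, "I": 1.0, "K": 1.0, "L": 1.0, "M": 1.0, "N": 1.0, "P": 20.26, "Q": 20.26, "R": 1.0, "S": 44.94, "T": 1.0, "V": -6.54, "W": 1.0, "Y": -6.54},
    "R": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 1.0, "F": 1.0, "G": -7.49, "H": 20.26, "I": 1.0, "K": 1.0, "L": 1.0, "M": 1.0, "N": 13.34, "P": 20.26, "Q": 20.26, "R": 58.28, "S": 44.94, "T": 1.0, "V": 1.0, "W": 58.28, "Y": -6.54},
    "S": {"A": 1.0, "C": 33.6, "D": 1.0, "E": 20.26, "F": 1.0, "G": 1.0, "H": 1.0, "I": 1.0, "K": 1.0, "L": 1.0, "M": 1.0, "N": 1.0, "P": 44.94, "Q": 20.26, "R": 20.26, "S": 20.26, "T": 1.0, "V": 1.0, "W": 1.0, "Y": 1.0},
    "T": {"A": 1.0, "C": 1.0, "D": 1.0, "E": 20.26, "F": 13.34, "G": -7.49, "H": 1.0, "I": 1.0, "K": 1.0, "L": 1.0, "M": 1.0, "N": -14.03, "P": 1.0, "Q": -6.54, "R": 1.0, "S": 1.0, "T": 1.0, "V": 1.0, "W": -14.03, "Y": 1.0},
    "V": {"A": 1.0, "C": 1.0, "D": -14.03, "E": 1.0, "F": 1.0, "G": -7.49, "H": 1.0, "I": 1.0, "K": -1.88, "L": 1.0, "M": 1.0, "N": 1.0, "P": 20.26, "Q": 1.0, "R": 1.0, "S": 1.0, "T": -7.49, "V": 1.0, "W": 1.0, "Y": -6.54},
    "W": {"A": -14.03, "C": 1.0, "D": 1.0, "E": 1.0, "F": 1.0, "G": -9.37, "H": 24.68, "I": 1.0, "K": 1.0, "L": 13.34, "M": 24.68, "N": 13.34, "P": 1.0, "Q": 1.0, "R": 1.0, "S": 1.0, "T": -14.03, "V": -7.49, "W": 1.0, "Y": 1.0},
    "Y": {"A": 24.68, "C": 1.0, "D": 24.68, "E": -6.54, "F": 1.0, "G": -7.49, "H": 13.34, "I": 1.0, "K": 1.0, "L": 1.0, "M": 44.94, "N": 1.0, "P": 13.34, "Q": 1.0, "R": -15.91, "S": 1.0, "T": -7.49, "V": 1.0, "W": -9.37, "Y": 13.34},
}

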