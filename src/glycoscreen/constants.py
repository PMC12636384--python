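"""Monoisotopic masses and mass offsets used throughout the pipeline.

All values in Da.
"""

# 20 standard amino-acid residue masses (monoisotopic, residue = AA - H2O)
RESIDUE_MASSES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.01056
PROTON = 1.007276
# iodoacetamide alkylation of cysteine
CARBAMIDOMETHYL = 57.02146

# glycan monosaccharide residue masses
HEX = 162.05282
HEXNAC = 203.07937
NEUAC = 291.09542
FUC = 146.05791

# C13 - C12 spacing used for isotope satellite detection
ISOTOPE_SPACING = 1.00335
# common negative-mode adduct offsets (replace H with Na / K)
ADDUCT_NA_MINUS_H = 21.98194
ADDUCT_K_MINUS_H = 37.95588
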