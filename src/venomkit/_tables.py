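"""Reference data tables.

Atomic masses and isotopic abundances are the IUPAC/CIAAW 2021 recommended
values (exact masses from AME2020) for the five elements found in unmodified
polypeptides.  All mass computation in the package goes through these tables
so that every reported mass is traceable to a single source.
"""

from __future__ import annotations

#: Mass of a proton (charge carrier in positive-mode ESI), Da.
PROTON = 1.007276466

#: Nominal mass spacing of a 13C isotope cluster, Da (adequate below ~10 kDa).
C13_SPACING = 1.00336

#: Per-element isotope tables: element -> list of (exact mass Da, abundance).
#: Sorted by mass; first entry is the lightest (monoisotopic) isotope.
ISOTOPES = {
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "H": [(1.00782503207, 0.999885), (2.01410177812, 0.000115)],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "O": [(15.99491461957, 0.99757), (16.99913175650, 0.00038), (17.99915961286, 0.00205)],
    "S": [(31.9720711744, 0.9499), (32.9714589098, 0.0075), (33.967867004, 0.0425),
          (35.96708071, 0.0001)],
}

#: Monoisotopic mass per element, Da.
MONO = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: Average (abundance-weighted) mass per element, Da.
AVERAGE = {el: sum(m * a for m, a in iso) / sum(a for _, a in iso)
           for el, iso in ISOTOPES.items()}

#: Residue (amino-acid minus water) elemental formulas, CHNOS counts.
RESIDUE_FORMULA = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER = {"H": 2, "O": 1}

#: Carbamidomethylation (iodoacetamide alkylation of Cys): +C2H3NO.
CAM_DELTA_MASS = 57.02146
CAM_DELTA_COMP = {"C": 2, "H": 3, "N": 1, "O": 1}

#: C-terminal amidation: -OH +NH2, i.e. composition delta -O +N +H.
AMIDE_DELTA_MASS = -0.9840156
AMIDE_DELTA_COMP = {"O": -1, "N": 1, "H": 1}

#: Per-disulfide mass delta: loss of two hydrogens.
DISULFIDE_DELTA_MASS = -2 * 1.0078250319

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Wimley-White interface hydrophobicity scale, kcal/mol for water ->
#: POPC interface transfer (negative = favors the membrane interface,
#: i.e. hydrophobic).  His taken in its neutral form.
WHITE_WIMLEY_INTERFACE = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24, "Q": 0.58,
    "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31, "L": -0.56, "K": 0.99,
    "M": -0.23, "F": -1.13, "P": 0.45, "S": 0.13, "T": 0.14, "W": -1.85,
    "Y": -0.94, "V": 0.07,
}

#: One codon per residue for reverse translation of synthetic libraries
#: (common E. coli codons; codon *optimization* is out of scope).  Codons
#: are chosen so that none ends in "A" or "AT", which guarantees that no
#: spurious ATG arises across codon junctions: the initiator ATG is the
#: only one in a synthetic coding sequence free of internal Met.
CODON = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATT",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}

AA20 = set(RESIDUE_FORMULA)
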