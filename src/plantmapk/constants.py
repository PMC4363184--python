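"""Shared physical constants and alphabets.

The residue mass table holds *average* (not monoisotopic) masses of amino
acid residues in Daltons, i.e. the free amino acid minus one water; a
peptide mass is the sum of residue masses plus one water.  The pKa table
drives the isoelectric-point solver and is deliberately a plain dict so a
caller can pass an alternative set.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_RESIDUE = "X"
GAP = "-"

WATER_MASS = 18.0153

#: Average residue masses (Da).
RESIDUE_MASS = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}

#: pKa values (EMBOSS-style set).  Basic groups: N-terminus, K, R, H;
#: acidic groups: C-terminus, D, E, C, Y.
DEFAULT_PKA = {
    "nterm": 8.6,
    "cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

BASIC_RESIDUES = ("K", "R", "H")
ACIDIC_RESIDUES = ("D", "E", "C", "Y")

#: The ten recognised activation-loop triplets (canonical TEY/TDY plus the
#: eight novel variants).
LOOP_VARIANTS = (
    "TEY",
    "TDY",
    "MEY",
    "TEM",
    "TQM",
    "TRM",
    "TVY",
    "TSY",
    "TEC",
    "TQY",
)

#: Legal activation-loop variants per phylogenetic group.  Group F carries
#: no diagnostic loop motif of its own (tree placement only) and is
#: generated with the ancestral TEY.
GROUP_LOOP_VARIANTS = {
    "A": ("TEY", "TQY"),
    "B": ("TEY", "MEY", "TEC", "TVY"),
    "C": ("TEY",),
    "D": ("TDY",),
    "E": ("TSY", "TEM", "TQM", "TRM"),
    "F": ("TEY",),
}
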