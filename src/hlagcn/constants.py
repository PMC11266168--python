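"""Frozen amino-acid tables used by the featurizers and edge detectors.

The seven physicochemical descriptors (steric parameter, hydrophobicity,
volume, polarizability, isoelectric point, helix probability, sheet
probability) are the AAPHY7 set of Meiler et al. (J Mol Model 7:360-369,
2001), widely used for residue-level graph featurization.
"""

from __future__ import annotations

# 20 standard residues, fixed order used for the BLOSUM block.
STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Eight-state secondary structure alphabet (DSSP convention) in the fixed
# one-hot order used by the residue featurizer.
SS8_STATES = ("H", "B", "E", "T", "G", "I", "S", "C")

# Hydrogen donor/acceptor classes of residue side chains.
DONOR_RESIDUES = set("RKW")
ACCEPTOR_RESIDUES = set("DE")
DONOR_ACCEPTOR_RESIDUES = set("NQHSTY")

# AAPHY7: steric parameter, hydrophobicity, volume, polarizability,
# isoelectric point, helix probability, sheet probability.
AAPHY7 = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94, 0.32, 0.42),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "S": (1.31, 0.06, 1.60, 0.13, 5.70, 0.20, 0.28),
    "R": (2.34, 0.29, 6.13, 1.01, 10.74, 0.36, 0.25),
    "K": (1.89, 0.22, 4.77, 0.99, 9.99, 0.32, 0.27),
    "H": (2.99, 0.23, 4.66, 0.70, 7.69, 0.27, 0.30),
    "D": (1.60, 0.11, 2.78, 0.81, 2.95, 0.25, 0.20),
    "E": (1.56, 0.15, 3.78, 1.45, 3.09, 0.42, 0.21),
    "N": (1.60, 0.13, 2.95, 0.22, 6.52, 0.21, 0.22),
    "Q": (1.56, 0.18, 3.95, 0.25, 5.65, 0.36, 0.25),
    "M": (2.35, 0.22, 4.43, 1.43, 5.71, 0.38, 0.32),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
}
# Unknown residues ('X') get the 20-residue mean.
AAPHY7_X = tuple(
    round(sum(AAPHY7[a][k] for a in STANDARD_AA) / 20.0, 6) for k in range(7)
)

# Side-chain heavy atoms carrying formal positive charge at physiological pH
# (used for ionic-bond detection) and their acidic counterparts.
BASIC_SIDECHAIN_N = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ACIDIC_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# Side-chain heavy atoms that can donate / accept hydrogen bonds, keyed by
# one-letter code; backbone N (donor) and O (acceptor) are handled separately.
SIDECHAIN_DONOR_ATOMS = {
    "R": ("NE", "NH1", "NH2"),
    "K": ("NZ",),
    "W": ("NE1",),
    "N": ("ND2",),
    "Q": ("NE2",),
    "H": ("ND1", "NE2"),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
}
SIDECHAIN_ACCEPTOR_ATOMS = {
    "D": ("OD1", "OD2"),
    "E": ("OE1", "OE2"),
    "N": ("OD1",),
    "Q": ("OE1",),
    "H": ("ND1", "NE2"),
    "S": ("OG",),
    "T": ("OG1",),
    "Y": ("OH",),
}

# Side-chain SMILES fragments attached to the alpha carbon.  Glycine has no
# side chain; proline is cyclic and gets a dedicated backbone unit.  Ring
# closure digits are local to each fragment, so reuse across residues is safe.
SIDECHAIN_SMILES = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "Q": "CCC(N)=O",
    "E": "CCC(=O)O",
    "H": "Cc1c[nH]cn1",
    "I": "C(C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "C(C)O",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
}
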