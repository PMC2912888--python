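"""Residue-level chemical constants: heavy-atom composition, chi-angle
definitions, name-symmetry groups and van der Waals radii.

Only the 20 standard amino acids are modelled; heavy atoms only.
"""
from __future__ import annotations

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Side-chain heavy atoms per residue type (PDB v3 names), in build order.
SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

AMINO_ACIDS = tuple(sorted(SIDE_CHAIN_ATOMS))

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# chi_k is the dihedral over CHI_ATOMS[res][k] (4 atom names).
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ALA": (), "GLY": (),
    "SER": (("N", "CA", "CB", "OG"),),
    "CYS": (("N", "CA", "CB", "SG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "VAL": (("N", "CA", "CB", "CG1"),),
    "PRO": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")),
    "LEU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "ASP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "ASN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")),
    "HIS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")),
    "PHE": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TYR": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "TRP": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")),
    "MET": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")),
    "GLU": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "GLN": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")),
    "LYS": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")),
    "ARG": (("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")),
}

N_CHI = {res: len(v) for res, v in CHI_ATOMS.items()}

# Atom-name swaps that describe the same chemistry (ring flips, equivalent
# carboxylate oxygens, ...). Each entry is a list of name-pair swaps applied
# together; RMSD and chi comparisons minimise over these permutations.
SYMMETRY_SWAPS: dict[str, tuple[tuple[tuple[str, str], ...], ...]] = {
    "PHE": ((("CD1", "CD2"), ("CE1", "CE2")),),
    "TYR": ((("CD1", "CD2"), ("CE1", "CE2")),),
    "ASP": ((("OD1", "OD2"),),),
    "GLU": ((("OE1", "OE2"),),),
    "ARG": ((("NH1", "NH2"),),),
    "LEU": ((("CD1", "CD2"),),),
    "VAL": ((("CG1", "CG2"),),),
}

# chi angles with a 180-degree name ambiguity (two-fold symmetric terminal group)
CHI_180_SYMMETRIC: dict[str, tuple[int, ...]] = {
    "ASP": (2,), "PHE": (2,), "TYR": (2,), "GLU": (3,),
}

# Van der Waals radii (Angstrom) used for atom-atom contact detection.
VDW_RADII = {"C": 1.548, "O": 1.348, "N": 1.400, "S": 1.808}


def element_of(atom_name: str) -> str:
    """Element inferred from a standard amino-acid heavy-atom name."""
    return atom_name[0]
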