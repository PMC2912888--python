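"""Ideal-geometry construction of side chains from chi angles.

Each side-chain heavy atom is defined by internal coordinates (bond length,
bond angle, torsion) relative to three previously placed atoms — a Z-matrix
per residue type. Torsions are either one of the residue's chi angles
(optionally offset, e.g. the second branch of a carboxylate at chi+180) or a
fixed value (planar ring completion).

Bond lengths/angles are standard ideal values (Engh-Huber-like); the table
is deliberately simple — fixtures and rotamer building need self-consistent
chi round-trips, not crystallographic realism.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import constants as C
from ._geom import dihedral, place_atom
from .errors import BuildError
from .structure_model import Atom, Residue

# torsion spec: ("chi", k, offset_degrees) or ("fix", value_degrees)
GeometryEntry = tuple[str, tuple[str, str, str], float, float, tuple]

_CB = ("CB", ("C", "N", "CA"), 1.53, 110.4, ("fix", 122.55))

GEOMETRY: dict[str, list[GeometryEntry]] = {
    "ALA": [_CB],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 1, 0.0))],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.81, 113.8, ("chi", 1, 0.0))],
    "THR": [_CB,
            ("OG1", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120.0))],
    "VAL": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 122.3))],
    "LEU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 122.6))],
    "ILE": [_CB,
            ("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.3)),
            ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi", 2, 0.0))],
    "PRO": [_CB,
            ("CG", ("N", "CA", "CB"), 1.49, 104.5, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.50, 106.1, ("chi", 2, 0.0))],
    "MET": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
            ("SD", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0.0)),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.8, ("chi", 3, 0.0))],
    "ASP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.5, ("chi", 2, 0.0)),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.5, ("chi", 2, 180.0))],
    "ASN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0.0)),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180.0))],
    "GLU": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.5, ("chi", 3, 0.0)),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.5, ("chi", 3, 180.0))],
    "GLN": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3, 0.0)),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, ("chi", 3, 180.0))],
    "LYS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3, 0.0)),
            ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, ("chi", 4, 0.0))],
    "ARG": [_CB,
            ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
            ("NE", ("CB", "CG", "CD"), 1.46, 112.0, ("chi", 3, 0.0)),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.5, ("chi", 4, 0.0)),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, ("fix", 0.0)),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, ("fix", 180.0))],
    "HIS": [_CB,
            ("CG", ("N", "CA", "CB"), 1.49, 113.8, ("chi", 1, 0.0)),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.3, ("fix", 180.0)),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, ("fix", 180.0))],
    # Phe/Tyr rings are built as exact regular hexagons so a 180-degree chi2
    # flip maps the ring onto itself with CD1/CD2 and CE1/CE2 names swapped.
    "PHE": [_CB,
            ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, ("fix", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, ("fix", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fix", 0.0))],
    "TYR": [_CB,
            ("CG", ("N", "CA", "CB"), 1.51, 113.8, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, ("fix", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, ("fix", 180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fix", 0.0)),
            ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, ("fix", 180.0))],
    "TRP": [_CB,
            ("CG", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 1, 0.0)),
            ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2, 0.0)),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, ("chi", 2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, ("fix", 180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, ("fix", 180.0)),
            ("CE3", ("CD1", "CG", "CD2"), 1.40, 133.9, ("fix", 180.0)),
            ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, ("fix", 180.0)),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.8, ("fix", 180.0)),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, ("fix", 0.0))],
    "GLY": [],
}


def build_side_chain_coords(backbone: Mapping[str, np.ndarray], res_type: str,
                            chi: Sequence[float],
                            geometry_table: Mapping[str, list[GeometryEntry]] | None = None,
                            ) -> dict[str, np.ndarray]:
    """Compute side-chain heavy-atom coordinates from chi angles.

    ``backbone`` must provide N, CA, C. Returns name -> coordinate mapping
    for the residue's side-chain atoms (empty for Gly).
    """
    table = GEOMETRY if geometry_table is None else geometry_table
    if res_type not in table:
        raise BuildError(f"no geometry for residue type {res_type}")
    for req in ("N", "CA", "C"):
        if req not in backbone:
            raise BuildError(f"missing backbone atom {req} for {res_type}")
    coords: dict[str, np.ndarray] = {k: np.asarray(v, float) for k, v in backbone.items()}
    out: dict[str, np.ndarray] = {}
    for name, (a, b, c), length, angle, tor in table[res_type]:
        if tor[0] == "chi":
            k, offset = tor[1], tor[2]
            if k > len(chi):
                raise BuildError(
                    f"{res_type} needs chi{k} but only {len(chi)} provided")
            torsion = chi[k - 1] + offset
        else:
            torsion = tor[1]
        pos = place_atom(coords[a], coords[b], coords[c], length, angle, torsion)
        coords[name] = pos
        out[name] = pos
    return out


def rebuild_side_chain(residue: Residue, chi: Sequence[float],
                       geometry_table=None) -> None:
    """Replace residue side-chain atoms in place with ideal-geometry atoms."""
    bb = {a.name: a.coords for a in residue.atoms if a.is_backbone}
    new = build_side_chain_coords(bb, residue.type, chi, geometry_table)
    backbone_atoms = [a for a in residue.atoms if a.is_backbone]
    side = [Atom(name=n, element=C.element_of(n), coords=xyz, is_backbone=False)
            for n, xyz in new.items()]
    residue.atoms = backbone_atoms + side


def measure_chi(residue: Residue) -> list[float] | None:
    """Chi angles (degrees) measured from coordinates; None if atoms missing."""
    defs = C.CHI_ATOMS.get(residue.type, ())
    out = []
    for quad in defs:
        pts = residue.coords_of(quad)
        if pts is None:
            return None
        out.append(dihedral(*pts))
    return out
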