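"""Protein structure data model and PDB input/output.

Structures are lists of residues holding heavy atoms only. Reading goes
through gemmi (altloc resolution, multi-model selection); writing emits
standard fixed-width ATOM records. Backbone dihedrals are derived from
coordinates on read, never stored in files.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from . import constants as C
from ._geom import dihedral
from .errors import EmptyStructureError, FormatError, ParseError

log = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class Atom:
    """A heavy atom: PDB name, element, coordinates (Angstrom), LJ class."""

    name: str
    element: str
    coords: np.ndarray
    lj_class: str | None = None
    is_backbone: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    """One amino-acid residue with author numbering and derived phi/psi."""

    type: str
    chain_id: str
    seq_id: int
    atoms: list[Atom] = field(default_factory=list)
    phi: float | None = None
    psi: float | None = None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords_of(self, names: Sequence[str]) -> np.ndarray | None:
        """Coordinate array for the named atoms, or None if any is missing."""
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                return None
            out.append(a.coords)
        return np.array(out)

    @property
    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_backbone]

    def validate_names(self) -> list[str]:
        """Return side-chain atom names not expected for this residue type."""
        expected = set(C.SIDE_CHAIN_ATOMS.get(self.type, ()))
        return [a.name for a in self.side_chain_atoms if a.name not in expected]


@dataclass
class Structure:
    """An ordered list of residues from one model of a PDB entry."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    model_index: int = 1
    resolution: float | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "Structure":
        new_res = []
        for r in self.residues:
            new_res.append(Residue(
                type=r.type, chain_id=r.chain_id, seq_id=r.seq_id,
                atoms=[replace(a, coords=a.coords.copy()) for a in r.atoms],
                phi=r.phi, psi=r.psi))
        return Structure(id=self.id, residues=new_res,
                         model_index=self.model_index, resolution=self.resolution)

    def all_atoms(self) -> Iterable[tuple[int, Residue, Atom]]:
        for i, res in enumerate(self.residues):
            for a in res.atoms:
                yield i, res, a


def compute_backbone_dihedrals(structure: Structure) -> None:
    """Fill phi/psi in place from coordinates; termini keep None."""
    res = structure.residues
    for i, r in enumerate(res):
        n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
        if n is None or ca is None or c is None:
            continue
        prev = res[i - 1] if i > 0 else None
        nxt = res[i + 1] if i + 1 < len(res) else None
        if prev is not None and prev.chain_id == r.chain_id:
            pc = prev.atom("C")
            if pc is not None:
                r.phi = dihedral(pc.coords, n.coords, ca.coords, c.coords)
        if nxt is not None and nxt.chain_id == r.chain_id:
            nn = nxt.atom("N")
            if nn is not None:
                r.psi = dihedral(n.coords, ca.coords, c.coords, nn.coords)


def read_structure(path: str | Path, model_index: int = 1,
                   chain_filter: Sequence[str] | None = None) -> Structure:
    """Read a PDB file into a Structure.

    Heavy atoms only (hydrogens dropped); altlocs resolved to the highest
    occupancy, ties broken toward altloc 'A'; HETATM and non-standard
    residues skipped with a logged count.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on garbage
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if model_index < 1 or model_index > len(st):
        raise ParseError(
            f"model_index {model_index} out of range (file has {len(st)} models)")
    model = st[model_index - 1]
    skipped = 0
    residues: list[Residue] = []
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for gres in chain:
            if gres.name not in C.SIDE_CHAIN_ATOMS or gres.het_flag == "H":
                skipped += 1
                continue
            # resolve altlocs: per atom name keep highest occupancy, tie -> 'A'
            by_name: dict[str, gemmi.Atom] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                cur = by_name.get(ga.name)
                if cur is None:
                    by_name[ga.name] = ga
                else:
                    key_new = (ga.occ, -ord(ga.altloc or "A"))
                    key_cur = (cur.occ, -ord(cur.altloc or "A"))
                    if key_new > key_cur:
                        by_name[ga.name] = ga
            atoms = [
                Atom(name=ga.name,
                     element=ga.element.name.upper(),
                     coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                     is_backbone=ga.name in C.BACKBONE_ATOMS or ga.name == "OXT")
                for ga in by_name.values()
            ]
            atoms.sort(key=lambda a: _atom_order(gres.name, a.name))
            residues.append(Residue(type=gres.name, chain_id=chain.name,
                                    seq_id=gres.seqid.num, atoms=atoms))
    if skipped:
        log.info("read_structure(%s): skipped %d HETATM/non-standard residues",
                 path.name, skipped)
    if not residues:
        raise EmptyStructureError(f"no standard protein residues read from {path}")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    out = Structure(id=path.stem, residues=residues,
                    model_index=model_index, resolution=resolution)
    compute_backbone_dihedrals(out)
    return out


def _atom_order(res_type: str, name: str) -> int:
    canon = list(C.BACKBONE_ATOMS) + list(C.SIDE_CHAIN_ATOMS.get(res_type, ())) + ["OXT"]
    try:
        return canon.index(name)
    except ValueError:
        return len(canon)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write standard PDB ATOM records (3-decimal coordinates)."""
    if not structure.residues:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    lines = []
    serial = 0
    prev_chain = None
    for res in structure.residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.type:>3s} "
                f"{res.chain_id[:1]}{res.seq_id:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}")
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def load_class_table(path: str | Path | None = None) -> dict[tuple[str, str], str]:
    """Load the (residue, atom) -> LJ class mapping.

    The shipped default has exactly 20 classes; "*" rows apply to every
    residue type.
    """
    if path is None:
        text = resources.files("tetrapot.data").joinpath("lj_classes.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[tuple[str, str], str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise FormatError(f"bad LJ class row: {line!r}")
        res, atom, cls = parts
        if res == "*":
            for rt in C.AMINO_ACIDS:
                table[(rt, atom)] = cls
        else:
            table[(res, atom)] = cls
    return table


@dataclass(frozen=True)
class LJParams:
    """Per-class well depths and radii with Lorentz-like combination.

    eps_ij = sqrt(eps_i * eps_j); r_min(i,j) = r_i + r_j, unless an explicit
    pair override exists (used for polar-polar optimal distances).
    """

    epsilon: Mapping[str, float]
    radius: Mapping[str, float]
    polar: Mapping[str, bool]
    rmin_overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)
    linearization_ratio: float = 0.89
    cutoff: float = 10.0

    def eps_ij(self, ci: str, cj: str) -> float:
        return math.sqrt(self.epsilon[ci] * self.epsilon[cj])

    def rmin_ij(self, ci: str, cj: str) -> float:
        key = (ci, cj) if ci <= cj else (cj, ci)
        if key in self.rmin_overrides:
            return self.rmin_overrides[key]
        return self.radius[ci] + self.radius[cj]

    @property
    def classes(self) -> list[str]:
        return sorted(self.epsilon)


def load_lj_params(path: str | Path | None = None) -> LJParams:
    """Load per-class epsilon/radius/polar table (shipped default: 20 classes)."""
    if path is None:
        text = resources.files("tetrapot.data").joinpath("lj_params.tsv").read_text()
    else:
        text = Path(path).read_text()
    eps: dict[str, float] = {}
    rad: dict[str, float] = {}
    pol: dict[str, bool] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"bad LJ parameter row: {line!r}")
        cls, e, r, p = parts
        eps[cls] = float(e)
        rad[cls] = float(r)
        pol[cls] = p == "1"
        if eps[cls] <= 0 or rad[cls] <= 0:
            raise FormatError(f"non-positive LJ parameter for class {cls}")
    return LJParams(epsilon=eps, radius=rad, polar=pol)


def assign_lj_classes(structure: Structure,
                      class_table: Mapping[tuple[str, str], str] | None = None,
                      ) -> Structure:
    """Attach an LJ class to every heavy atom (in place; returns structure).

    Atoms absent from the table get the explicit UNCLASSIFIED marker and are
    excluded from Lennard-Jones sums.
    """
    if class_table is None:
        class_table = load_class_table()
    unknown = 0
    for _, res, atom in structure.all_atoms():
        cls = class_table.get((res.type, atom.name))
        if cls is None:
            atom.lj_class = UNCLASSIFIED
            unknown += 1
        else:
            atom.lj_class = cls
    if unknown:
        log.info("assign_lj_classes: %d atoms left unclassified", unknown)
    return structure
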