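"""Synthetic structure, corpus and decoy generators.

Everything here is seed-deterministic and returns assertion-ready ground
truth alongside the data, so the whole pipeline is testable without
downloading structures. Covalent geometry is ideal (standard bond lengths
and angles); crystallographic noise is not emulated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from ._geom import place_atom
from .contact_statistics import (AtomPairDefinition, randomize_side_chains)
from .errors import InfeasibleGeometryError, ParameterError
from .rotamer_library import Rotamer, RotamerLibrary
from .sidechain_geometry import build_side_chain_coords, measure_chi
from .structure_model import (Atom, Residue, Structure,
                              compute_backbone_dihedrals)

# ideal backbone internal coordinates
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_CNCA, _ANG_NCAC, _ANG_CACN, _ANG_CACO = 121.7, 111.2, 116.2, 120.8

CONFORMATIONS = {"helix": (-60.0, -45.0), "extended": (-140.0, 135.0)}


def _backbone_chain(n: int, phi: list[float], psi: list[float]
                    ) -> list[dict[str, np.ndarray]]:
    """Sequential (NeRF) backbone construction; omega fixed at 180."""
    out: list[dict[str, np.ndarray]] = []
    N = np.zeros(3)
    CA = np.array([_N_CA, 0.0, 0.0])
    Cc = place_atom(np.array([-0.5, 1.2, 0.0]), N, CA, _CA_C, _ANG_NCAC, 120.0)
    for i in range(n):
        bb = {"N": N, "CA": CA, "C": Cc}
        bb["O"] = place_atom(bb["N"], bb["CA"], bb["C"], _C_O, _ANG_CACO,
                             psi[i] + 180.0)
        out.append(bb)
        if i + 1 < n:
            N2 = place_atom(bb["N"], bb["CA"], bb["C"], _C_N, _ANG_CACN, psi[i])
            CA2 = place_atom(bb["CA"], bb["C"], N2, _N_CA, _ANG_CNCA, 180.0)
            C2 = place_atom(bb["C"], N2, CA2, _CA_C, _ANG_NCAC, phi[i + 1])
            N, CA, Cc = N2, CA2, C2
    return out


def _residue_from_parts(res_type: str, chain_id: str, seq_id: int,
                        bb: dict[str, np.ndarray],
                        side: dict[str, np.ndarray]) -> Residue:
    atoms = [Atom(name=n, element=C.element_of(n), coords=bb[n], is_backbone=True)
             for n in ("N", "CA", "C", "O")]
    atoms += [Atom(name=n, element=C.element_of(n), coords=xyz, is_backbone=False)
              for n, xyz in side.items()]
    return Residue(type=res_type, chain_id=chain_id, seq_id=seq_id, atoms=atoms)


def make_toy_rotamer_library(seed: int = 0, grid: float = 120.0
                             ) -> RotamerLibrary:
    """A small, normalised backbone-dependent library for tests.

    Covers all 18 chi-bearing residue types at every phi/psi bin of a coarse
    grid; chi1 takes the three staggered wells (gauche-, gauche+, trans) with
    probabilities 0.5/0.3/0.2 and seed-jittered means.
    """
    rng = np.random.default_rng(seed)
    lib = RotamerLibrary(grid=grid)
    nb = lib.n_bins
    extra_chi = {
        "LEU": [170.0], "ILE": [170.0], "MET": [180.0, 75.0],
        "GLU": [180.0, -10.0], "GLN": [180.0, 20.0],
        "LYS": [180.0, 180.0, 180.0], "ARG": [180.0, 180.0, -85.0],
        "ASP": [-20.0], "ASN": [-30.0], "HIS": [80.0], "PHE": [90.0],
        "TYR": [90.0], "TRP": [75.0],
    }
    for res in C.AMINO_ACIDS:
        n_chi = C.N_CHI[res]
        if n_chi == 0:
            continue
        if res == "PRO":
            base = [([25.0, -35.0], 0.6), ([-25.0, 35.0], 0.4)]
        else:
            tail = extra_chi.get(res, [])[: n_chi - 1]
            base = [([w] + tail, p)
                    for w, p in ((-60.0, 0.5), (60.0, 0.3), (180.0, 0.2))]
        for pb in range(nb):
            for sb in range(nb):
                rots = []
                probs = np.array([p for _, p in base])
                probs = probs + rng.uniform(-0.02, 0.02, len(probs))
                probs = probs / probs.sum()
                for (chi, _), p in zip(base, probs):
                    jitter = rng.uniform(-3.0, 3.0, len(chi))
                    rots.append(Rotamer(
                        residue_type=res,
                        chi=tuple(float(c + j) for c, j in zip(chi, jitter)),
                        sigma=tuple([8.0] * len(chi)),
                        probability=float(p)))
                lib.entries[(res, pb, sb)] = rots
    return lib


def make_toy_structure(sequence: str, seed: int = 0,
                       conformation: str = "helix",
                       library: RotamerLibrary | None = None,
                       chain_id: str = "A",
                       structure_id: str = "toy") -> Structure:
    """An ideal-geometry chain with library-drawn side chains.

    ``sequence`` is one-letter code; the backbone is an ideal helix or
    extended strand; each side chain is a rotamer drawn at random (seeded)
    from the library group at the residue's phi/psi.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 2:
        raise ParameterError("need at least 2 residues")
    bad = [ch for ch in sequence if ch not in C.ONE_TO_THREE]
    if bad:
        raise ParameterError(f"invalid residue letters: {bad}")
    if conformation not in CONFORMATIONS:
        raise ParameterError(f"unknown conformation {conformation!r}")
    phi0, psi0 = CONFORMATIONS[conformation]
    n = len(sequence)
    rng = np.random.default_rng(seed)
    backbones = _backbone_chain(n, [phi0] * n, [psi0] * n)
    if library is None:
        library = make_toy_rotamer_library(seed)
    residues = []
    for i, (ch, bb) in enumerate(zip(sequence, backbones)):
        rt = C.ONE_TO_THREE[ch]
        side: dict[str, np.ndarray] = {}
        if rt == "ALA":
            side = build_side_chain_coords(bb, rt, [])
        elif C.N_CHI[rt] > 0:
            group = library.group(rt, phi0, psi0)
            rot = group[int(rng.integers(len(group)))]
            side = build_side_chain_coords(bb, rt, rot.chi)
        residues.append(_residue_from_parts(rt, chain_id, i + 1, bb, side))
    s = Structure(id=structure_id, residues=residues)
    compute_backbone_dihedrals(s)
    return s


@dataclass
class PlantedGeometrySpec:
    """Recipe for a corpus with one dominant contact geometry.

    ``quadruple`` is the target (d11, d12, d21, d22) between the chosen atom
    pairs; signal contacts reproduce it (plus optional jitter), noise
    contacts are random contact-compatible placements.
    """

    pair: tuple[str, str]
    quadruple: tuple[float, float, float, float]
    n_signal: int
    n_noise: int
    jitter: float = 0.0
    seed: int = 0
    atoms_a: tuple[str, str] | None = None
    atoms_b: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if any(not (0.0 < d < 10.0) for d in self.quadruple):
            raise ParameterError("quadruple distances must be in (0, 10)")
        if self.n_signal < 0 or self.n_noise < 0:
            raise ParameterError("contact counts must be non-negative")


@dataclass
class PlantedCorpus:
    structures: list[Structure]
    definition: AtomPairDefinition
    quadruple: tuple[float, float, float, float]
    spec: PlantedGeometrySpec = field(repr=False, default=None)


def feasible_quadruple(pair: tuple[str, str],
                       atoms_a: tuple[str, str] | None = None,
                       atoms_b: tuple[str, str] | None = None,
                       offset: tuple[float, float, float] = (0.1344, 4.2635, -0.0014),
                       direction: tuple[float, float, float] = (0.8701, -0.0732, -0.4874),
                       ) -> tuple[float, float, float, float]:
    """An exactly-realisable target quadruple for make_planted_corpus.

    Places the second residue's atom pair at ``offset`` along ``direction``
    relative to the first pair and returns the resulting four distances,
    which are consistent with the residues' fixed intra-pair separations.
    """
    t1, t2 = pair
    atoms_a = atoms_a or tuple(C.SIDE_CHAIN_ATOMS[t1][-2:])
    atoms_b = atoms_b or tuple(C.SIDE_CHAIN_ATOMS[t2][-2:])
    pa = _template_residue(t1, "A", 1).coords_of(atoms_a)
    pb = _template_residue(t2, "B", 1).coords_of(atoms_b)
    r1 = float(np.linalg.norm(pa[1] - pa[0]))
    r2 = float(np.linalg.norm(pb[1] - pb[0]))
    a1 = np.zeros(3)
    a2 = np.array([r1, 0.0, 0.0])
    b1 = np.asarray(offset, float)
    d = np.asarray(direction, float)
    b2 = b1 + r2 * d / np.linalg.norm(d)
    return (float(np.linalg.norm(a1 - b1)), float(np.linalg.norm(a1 - b2)),
            float(np.linalg.norm(a2 - b1)), float(np.linalg.norm(a2 - b2)))


def embed_quadruple(quad: tuple[float, float, float, float],
                    r1: float, r2: float) -> np.ndarray:
    """Embed the 4 atoms (a1, a2, b1, b2) in 3-space.

    ``r1``/``r2`` are the fixed intra-residue separations |a1-a2|, |b1-b2|;
    the cross distances are the quadruple. Raises InfeasibleGeometryError
    naming the violated bound when no embedding exists.
    """
    d11, d12, d21, d22 = quad
    a1 = np.zeros(3)
    a2 = np.array([r1, 0.0, 0.0])
    x1 = (r1 * r1 + d11 * d11 - d21 * d21) / (2 * r1)
    y1sq = d11 * d11 - x1 * x1
    if y1sq < -1e-9:
        raise InfeasibleGeometryError(
            f"d11={d11}, d21={d21} violate the triangle bound with |a1-a2|={r1:.3f}")
    y1 = math.sqrt(max(y1sq, 0.0))
    b1 = np.array([x1, y1, 0.0])
    x2 = (r1 * r1 + d12 * d12 - d22 * d22) / (2 * r1)
    rho_sq = d12 * d12 - x2 * x2
    if rho_sq < -1e-9:
        raise InfeasibleGeometryError(
            f"d12={d12}, d22={d22} violate the triangle bound with |a1-a2|={r1:.3f}")
    rho_sq = max(rho_sq, 0.0)
    if y1 < 1e-9:
        # b1 on the a1-a2 axis: any point at the right radii works if |b1-b2|=r2
        z2sq = rho_sq
        y2 = 0.0
        if abs(np.linalg.norm(np.array([x2, 0.0, math.sqrt(max(z2sq, 0))]) - b1)
               - r2) > 1e-6:
            raise InfeasibleGeometryError(
                "degenerate collinear embedding incompatible with |b1-b2|")
    else:
        y2 = ((x2 - x1) ** 2 + rho_sq + y1 * y1 - r2 * r2) / (2 * y1)
        z2sq = rho_sq - y2 * y2
        if z2sq < -1e-9:
            raise InfeasibleGeometryError(
                f"quadruple {quad} cannot close with |b1-b2|={r2:.3f} "
                f"(z^2 = {z2sq:.4f} < 0)")
    b2 = np.array([x2, y2, math.sqrt(max(z2sq, 0.0))])
    return np.stack([a1, a2, b1, b2])


_TEMPLATE_CHI = {
    "PRO": [25.0, -35.0],
}


def _template_residue(res_type: str, chain_id: str, seq_id: int) -> Residue:
    """A free-standing residue on an ideal backbone with canonical chi."""
    bb = _backbone_chain(1, [CONFORMATIONS["extended"][0]],
                         [CONFORMATIONS["extended"][1]])[0]
    n_chi = C.N_CHI[res_type]
    chi = _TEMPLATE_CHI.get(res_type, [-60.0] + [180.0] * max(n_chi - 1, 0))[:n_chi]
    side = (build_side_chain_coords(bb, res_type, chi)
            if res_type != "GLY" else {})
    return _residue_from_parts(res_type, chain_id, seq_id, bb, side)


def _transform_residue(res: Residue, rot: np.ndarray, shift: np.ndarray) -> None:
    for a in res.atoms:
        a.coords = rot @ a.coords + shift


def _align_pair(res: Residue, names: tuple[str, str],
                target: np.ndarray, roll: float) -> None:
    """Rigidly move ``res`` so the two named atoms land on target[0], target[1].

    The free rotation about the pair axis is fixed by ``roll`` (radians)."""
    p = res.coords_of(names)
    v_from = p[1] - p[0]
    v_to = target[1] - target[0]
    u = v_from / np.linalg.norm(v_from)
    w = v_to / np.linalg.norm(v_to)
    axis = np.cross(u, w)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, w))
    if s < 1e-12:
        R = np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(u, u)
    else:
        k = axis / s
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
    # roll about the target axis
    k = w
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    Rroll = np.eye(3) + math.sin(roll) * K + (1 - math.cos(roll)) * (K @ K)
    R = Rroll @ R
    shift = target[0] - R @ p[0]
    _transform_residue(res, R, shift)


def make_planted_corpus(spec: PlantedGeometrySpec) -> PlantedCorpus:
    """Structures whose contacts reproduce a planted distance quadruple.

    Each structure holds one residue pair on separate chains; ``n_signal``
    structures realise the target quadruple (+- jitter), ``n_noise`` are
    random contact-compatible placements.
    """
    t1, t2 = spec.pair
    key = (t1, t2) if t1 <= t2 else (t2, t1)
    if key != spec.pair:
        raise ParameterError("pair must be in canonical (sorted) order")
    atoms_a = spec.atoms_a or tuple(C.SIDE_CHAIN_ATOMS[t1][-2:])
    atoms_b = spec.atoms_b or tuple(C.SIDE_CHAIN_ATOMS[t2][-2:])
    if t1 == t2 and atoms_a != atoms_b:
        raise ParameterError("homotypic pair needs identical atom choices")
    definition = AtomPairDefinition(pair=key, atoms_a=atoms_a, atoms_b=atoms_b)
    rng = np.random.default_rng(spec.seed)

    ra = _template_residue(t1, "A", 1)
    rb = _template_residue(t2, "B", 1)
    pa = ra.coords_of(atoms_a)
    pb = rb.coords_of(atoms_b)
    if pa is None or pb is None:
        raise ParameterError("atom pair not present in residue template")
    r1 = float(np.linalg.norm(pa[1] - pa[0]))
    r2 = float(np.linalg.norm(pb[1] - pb[0]))
    # fail fast on an infeasible target before any sampling
    embed_quadruple(spec.quadruple, r1, r2)

    structures: list[Structure] = []

    def one_structure(idx: int, quad) -> Structure:
        points = embed_quadruple(tuple(quad), r1, r2)
        a = _template_residue(t1, "A", 1)
        b = _template_residue(t2, "B", 1)
        _align_pair(a, atoms_a, points[:2], rng.uniform(0, 2 * math.pi))
        _align_pair(b, atoms_b, points[2:], rng.uniform(0, 2 * math.pi))
        return Structure(id=f"planted_{idx}", residues=[a, b])

    idx = 0
    for _ in range(spec.n_signal):
        for _attempt in range(50):
            quad = np.asarray(spec.quadruple, float)
            if spec.jitter > 0:
                quad = quad + rng.normal(0.0, spec.jitter, 4)
                quad = np.clip(quad, 0.3, 9.7)
            try:
                structures.append(one_structure(idx, quad))
                break
            except InfeasibleGeometryError:
                if spec.jitter == 0:
                    raise
        else:
            raise InfeasibleGeometryError(
                "could not realise a jittered quadruple in 50 attempts")
        idx += 1

    # noise: quadruples drawn uniformly over the contact-compatible,
    # embeddable region of distance space
    for _ in range(spec.n_noise):
        for _attempt in range(2000):
            quad = rng.uniform(1.5, 9.5, 4)
            if quad.min() >= 5.0:
                continue
            try:
                structures.append(one_structure(idx, quad))
                idx += 1
                break
            except InfeasibleGeometryError:
                continue
        else:
            raise InfeasibleGeometryError("noise sampling failed repeatedly")

    return PlantedCorpus(structures=structures, definition=definition,
                         quadruple=spec.quadruple, spec=spec)


@dataclass
class Decoy:
    """A perturbed copy of a native structure with its deviation labels."""

    structure: Structure
    level: int
    sidechain_rmsd: float
    backbone_rmsd: float


def make_decoy_set(native: Structure, n_decoys: int,
                   perturbation_levels: tuple[int, ...] = (1,),
                   seed: int = 0,
                   library: RotamerLibrary | None = None) -> list[Decoy]:
    """Decoys: level 1 randomizes side chains on the native backbone;
    levels >= 2 additionally perturb backbone phi/psi before rebuilding."""
    from .evaluation import sidechain_rmsd  # local import to avoid a cycle
    if n_decoys == 0:
        return []
    if library is None:
        library = make_toy_rotamer_library(seed)
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_decoys):
        level = perturbation_levels[k % len(perturbation_levels)]
        base = native
        if level >= 2:
            base = _perturb_backbone(native, rng, sigma=4.0 * (level - 1))
        decoy = randomize_side_chains(base, library,
                                      int(rng.integers(2 ** 31 - 1)))
        decoy.id = f"{native.id}_decoy{k}"
        bb_rmsd = _backbone_rmsd(native, decoy)
        try:
            sc_rmsd = sidechain_rmsd(decoy, native)
        except Exception:
            sc_rmsd = float("nan")
        out.append(Decoy(structure=decoy, level=level,
                         sidechain_rmsd=sc_rmsd, backbone_rmsd=bb_rmsd))
    return out


def _backbone_rmsd(a: Structure, b: Structure) -> float:
    pa = np.array([r.atom("CA").coords for r in a.residues if r.atom("CA")])
    pb = np.array([r.atom("CA").coords for r in b.residues if r.atom("CA")])
    if len(pa) != len(pb) or len(pa) == 0:
        return float("nan")
    return float(np.sqrt(((pa - pb) ** 2).sum(-1).mean()))


def _perturb_backbone(native: Structure, rng: np.random.Generator,
                      sigma: float) -> Structure:
    """Rebuild the backbone with noisy phi/psi, carrying over native chi."""
    n = len(native.residues)
    phi = [(r.phi if r.phi is not None else -120.0) + rng.normal(0, sigma)
           for r in native.residues]
    psi = [(r.psi if r.psi is not None else 130.0) + rng.normal(0, sigma)
           for r in native.residues]
    backbones = _backbone_chain(n, phi, psi)
    residues = []
    for r, bb in zip(native.residues, backbones):
        chi = measure_chi(r) or []
        side = (build_side_chain_coords(bb, r.type, chi)
                if r.type != "GLY" else {})
        residues.append(_residue_from_parts(r.type, r.chain_id, r.seq_id, bb, side))
    s = Structure(id=native.id + "_bbperturb", residues=residues)
    compute_backbone_dihedrals(s)
    return s
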