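"""Accuracy metrics and decoy discrimination.

Side-chain RMSD (pooled heavy-atom, symmetry-aware), chi1/chi1+2 accuracy at
+-15 degrees, normalized RMSD against the random-rotamer baseline, the 0-100
atom-atom contact score, solvent-accessibility burial classification, and
rank/Z-score statistics over decoy sets.

Model and native are compared on identical backbones — no superposition is
performed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import constants as C
from ._geom import wrap_angle
from .errors import ParameterError
from .rotamer_library import RotamerLibrary, build_side_chain
from .sidechain_geometry import measure_chi
from .structure_model import Residue, Structure

log = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    rmsd_all: float
    rmsd_buried: float | None
    rmsd_exposed: float | None
    chi1_pct: float | None
    chi12_pct: float | None
    nrmsd: dict[int, float | None]
    contact_score: float | None
    burial: dict[int, str]


@dataclass
class DecoyRanking:
    scores: list[float]
    reference_index: int
    rank: int
    z_score: float | None


# -- side-chain RMSD --------------------------------------------------------

def _symmetry_variants(res_type: str, names: list[str]) -> list[list[str]]:
    variants = [names]
    for swaps in C.SYMMETRY_SWAPS.get(res_type, ()):
        mapping = {}
        for a, b in swaps:
            mapping[a] = b
            mapping[b] = a
        variants.append([mapping.get(n, n) for n in names])
    return variants


def residue_sidechain_rmsd(model_res: Residue, native_res: Residue
                           ) -> tuple[float, int]:
    """(RMSD, atom count) over common side-chain heavy atoms, minimised over
    the residue's chemically equivalent atom-name permutations."""
    if model_res.type != native_res.type:
        raise ParameterError(
            f"residue type mismatch: {model_res.type} vs {native_res.type}")
    names = [a.name for a in model_res.side_chain_atoms
             if native_res.atom(a.name) is not None]
    if not names:
        return 0.0, 0
    m = np.array([model_res.atom(n).coords for n in names])
    best = None
    for variant in _symmetry_variants(model_res.type, names):
        nat = native_res.coords_of(variant)
        if nat is None:
            continue
        ss = float(((m - nat) ** 2).sum())
        if best is None or ss < best:
            best = ss
    return math.sqrt(best / len(names)), len(names)


def _paired_residues(model: Structure, native: Structure
                     ) -> list[tuple[int, Residue, Residue]]:
    if len(model) != len(native):
        raise ParameterError("model and native have different residue counts")
    out = []
    for i, (mr, nr) in enumerate(zip(model.residues, native.residues)):
        if mr.type != nr.type:
            raise ParameterError(f"residue identity mismatch at index {i}")
        out.append((i, mr, nr))
    return out


def sidechain_rmsd(model: Structure, native: Structure,
                   selection: str = "all") -> float | dict[int, float]:
    """Pooled side-chain heavy-atom RMSD over a residue selection.

    ``selection``: all | buried | exposed | interface | per-residue. Burial
    is classified on the native structure; "per-residue" returns a dict.
    """
    pairs = _paired_residues(model, native)
    if selection in ("buried", "exposed"):
        burial = classify_burial(native)
        pairs = [(i, m, n) for i, m, n in pairs if burial.get(i) == selection]
    elif selection == "interface":
        iface = _interface_residues(native)
        pairs = [(i, m, n) for i, m, n in pairs if i in iface]
    elif selection == "per-residue":
        out = {}
        for i, m, n in pairs:
            r, cnt = residue_sidechain_rmsd(m, n)
            if cnt:
                out[i] = r
        return out
    elif selection != "all":
        raise ParameterError(f"unknown selection {selection!r}")
    ss, count = 0.0, 0
    for i, m, n in pairs:
        expected = set(C.SIDE_CHAIN_ATOMS[m.type])
        present = {a.name for a in n.side_chain_atoms}
        if m.type != "GLY" and not expected <= present:
            log.warning("residue %d (%s): incomplete native side chain; excluded",
                        i, m.type)
            continue
        r, cnt = residue_sidechain_rmsd(m, n)
        ss += r * r * cnt
        count += cnt
    return math.sqrt(ss / count) if count else 0.0


def _interface_residues(structure: Structure, cutoff: float = 5.0) -> set[int]:
    out = set()
    res = structure.residues
    for i, ri in enumerate(res):
        sci = [a.coords for a in ri.side_chain_atoms]
        if not sci:
            continue
        for j, rj in enumerate(res):
            if rj.chain_id == ri.chain_id:
                continue
            for b in rj.atoms:
                d = np.linalg.norm(np.array(sci) - b.coords, axis=1).min()
                if d < cutoff:
                    out.add(i)
                    break
            else:
                continue
            break
    return out


# -- burial -----------------------------------------------------------------

_REF_SASA_CACHE: dict[str, float] = {}


def _reference_sidechain_sasa(res_type: str, probe_radius: float = 1.4) -> float:
    """Maximum side-chain accessibility: the central residue of an extended
    Gly-X-Gly tripeptide (Gly itself uses its full-residue area)."""
    key = f"{res_type}:{probe_radius}"
    if key not in _REF_SASA_CACHE:
        from .fixtures import make_toy_structure
        one = C.THREE_TO_ONE[res_type]
        tri = make_toy_structure(f"G{one}G", seed=0, conformation="extended")
        areas = _atom_sasa(tri, probe_radius)
        mid = tri.residues[1]
        names = ([a.name for a in mid.atoms] if res_type == "GLY"
                 else [a.name for a in mid.side_chain_atoms])
        _REF_SASA_CACHE[key] = sum(areas[(1, n)] for n in names)
    return _REF_SASA_CACHE[key]


def _atom_sasa(structure: Structure, probe_radius: float = 1.4
               ) -> dict[tuple[int, str], float]:
    """Shrake-Rupley solvent-accessible area per (residue index, atom name)."""
    import biotite.structure as struc
    atoms = list(structure.all_atoms())
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for _, _, a in atoms])
    arr.chain_id = np.array([r.chain_id for _, r, _ in atoms])
    arr.res_id = np.array([i + 1 for i, _, _ in atoms])
    arr.res_name = np.array([r.type for _, r, _ in atoms])
    arr.atom_name = np.array([a.name for _, _, a in atoms])
    arr.element = np.array([a.element for _, _, a in atoms])
    areas = struc.sasa(arr, probe_radius=probe_radius, point_number=300,
                       vdw_radii="Single")
    return {(i, a.name): float(v)
            for (i, _, a), v in zip(atoms, areas)}


def classify_burial(structure: Structure, threshold: float = 0.20,
                    probe_radius: float = 1.4) -> dict[int, str]:
    """Label residues buried/exposed by relative side-chain accessibility.

    Relative accessibility is the residue's side-chain solvent-accessible
    area divided by its maximum in an extended Gly-X-Gly context; at most
    ``threshold`` (default 20%) means buried. Gly uses full-residue area.
    """
    areas = _atom_sasa(structure, probe_radius)
    out = {}
    for i, res in enumerate(structure.residues):
        names = ([a.name for a in res.atoms] if res.type == "GLY"
                 else [a.name for a in res.side_chain_atoms])
        if not names:
            out[i] = "exposed"
            continue
        area = sum(areas.get((i, n), 0.0) for n in names)
        ref = _reference_sidechain_sasa(res.type, probe_radius)
        rel = area / ref if ref > 0 else 1.0
        out[i] = "buried" if rel <= threshold else "exposed"
    return out


# -- chi accuracy -----------------------------------------------------------

def _chi_deviation(res_type: str, k: int, chi_model: float,
                   chi_native: float) -> float:
    d = abs(wrap_angle(chi_model - chi_native))
    if k in C.CHI_180_SYMMETRIC.get(res_type, ()):
        d = min(d, abs(wrap_angle(chi_model - chi_native + 180.0)))
    return d


def chi_accuracy(model: Structure, native: Structure,
                 tolerance: float = 15.0) -> tuple[float | None, float | None]:
    """(chi1 %, chi1+2 %) of residues within ``tolerance`` degrees (inclusive),
    180-degree terminal symmetries resolved to the smaller deviation."""
    n1 = ok1 = n12 = ok12 = 0
    for i, m, n in _paired_residues(model, native):
        cm, cn = measure_chi(m), measure_chi(n)
        if cm is None or cn is None or not cm:
            continue
        d1 = _chi_deviation(m.type, 1, cm[0], cn[0])
        n1 += 1
        ok1 += d1 <= tolerance
        if len(cm) >= 2:
            d2 = _chi_deviation(m.type, 2, cm[1], cn[1])
            n12 += 1
            ok12 += (d1 <= tolerance) and (d2 <= tolerance)
    return (100.0 * ok1 / n1 if n1 else None,
            100.0 * ok12 / n12 if n12 else None)


# -- normalized RMSD --------------------------------------------------------

def nrmsd(model: Structure, native: Structure, library: RotamerLibrary
          ) -> dict[int, float | None]:
    """Per-residue RMSD divided by the expected RMSD of random placement.

    The baseline is the probability-weighted mean RMSD of the residue's
    library rotamers rebuilt on the native backbone (deterministic; 1.0
    means random-level accuracy). None where the baseline is ~0 or no
    rotamers exist.
    """
    out: dict[int, float | None] = {}
    for i, m, n in _paired_residues(model, native):
        if C.N_CHI[m.type] == 0:
            continue
        try:
            group = library.group(n.type, n.phi, n.psi)
        except KeyError:
            out[i] = None
            continue
        if n.coords_of(("N", "CA", "C")) is None:
            out[i] = None
            continue
        baseline = 0.0
        scratch = Residue(type=n.type, chain_id=n.chain_id, seq_id=n.seq_id,
                          atoms=[a for a in n.atoms if a.is_backbone])
        from .structure_model import Atom
        for rot in group:
            coords = build_side_chain(n, rot)
            scratch.atoms = ([a for a in n.atoms if a.is_backbone]
                             + [Atom(name=nm, element=C.element_of(nm),
                                     coords=xyz, is_backbone=False)
                                for nm, xyz in coords.items()])
            r, cnt = residue_sidechain_rmsd(scratch, n)
            if cnt:
                baseline += rot.probability * r
        if baseline < 1e-9:
            out[i] = None
            continue
        r, cnt = residue_sidechain_rmsd(m, n)
        out[i] = r / baseline if cnt else None
    return out


# -- contact score ----------------------------------------------------------

#: (allowed further, allowed closer, score), best first
_CONTACT_INTERVALS = ((0.125, 0.0675, 4), (0.25, 0.125, 3),
                      (0.5, 0.25, 2), (1.0, 0.5, 1))


def _atom_contacts(structure: Structure) -> dict[tuple, float]:
    """ScSc and ScMc atom-atom contacts: heavy-atom pairs from distinct,
    non-adjacent residues with at least one side-chain atom, closer than the
    sum of van der Waals radii plus 1 A. Keyed by (res i, name, res j, name)."""
    from scipy.spatial import cKDTree
    atoms = list(structure.all_atoms())
    coords = np.array([a.coords for _, _, a in atoms])
    radii = np.array([C.VDW_RADII.get(a.element, 1.7) for _, _, a in atoms])
    res_idx = np.array([i for i, _, _ in atoms])
    is_bb = np.array([a.is_backbone for _, _, a in atoms])
    tree = cKDTree(coords)
    max_cut = 2 * radii.max() + 1.0
    out = {}
    res = structure.residues
    for a, b in tree.query_pairs(max_cut):
        i, j = res_idx[a], res_idx[b]
        if i == j:
            continue
        if res[i].chain_id == res[j].chain_id and abs(i - j) <= 1:
            continue
        if is_bb[a] and is_bb[b]:
            continue
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d < radii[a] + radii[b] + 1.0:
            if (i, atoms[a][2].name) > (j, atoms[b][2].name):
                a, b, i, j = b, a, j, i
            out[(int(i), atoms[a][2].name, int(j), atoms[b][2].name)] = d
    return out


def contact_score(model: Structure, native: Structure) -> float | None:
    """0-100 score of how well model atom-atom contact distances reproduce
    the native ones (4/3/2/1 points by nested tolerance intervals, scaled by
    25 / native contact count). None if the native has no contacts."""
    _paired_residues(model, native)  # validates correspondence
    native_contacts = _atom_contacts(native)
    if not native_contacts:
        return None
    model_contacts = _atom_contacts(model)
    total = 0
    for key, dm in model_contacts.items():
        dn = native_contacts.get(key)
        if dn is None:
            continue
        delta = dm - dn
        for further, closer, score in _CONTACT_INTERVALS:
            if -closer <= delta <= further:
                total += score
                break
    return 25.0 * total / len(native_contacts)


# -- decoy ranking ----------------------------------------------------------

def rank_decoys(scores: list[float], reference_index: int) -> DecoyRanking:
    """Rank (1 = lowest score) and Z-score of a designated reference.

    Z = (mean - score_ref) / population stdev: positive when the reference
    scores better (lower) than the average. Ties share the better rank."""
    if len(scores) < 2:
        raise ParameterError("need at least 2 scores")
    ref = scores[reference_index]
    rank = 1 + sum(1 for s in scores if s < ref)
    arr = np.asarray(scores, float)
    sd = float(arr.std())  # population stdev
    z = (float(arr.mean()) - ref) / sd if sd > 0 else None
    return DecoyRanking(scores=list(scores), reference_index=reference_index,
                        rank=rank, z_score=z)


def evaluate(model: Structure, native: Structure,
             library: RotamerLibrary | None = None) -> EvaluationReport:
    """Full accuracy report of a model against its native structure."""
    burial = classify_burial(native)
    chi1, chi12 = chi_accuracy(model, native)
    return EvaluationReport(
        rmsd_all=sidechain_rmsd(model, native, "all"),
        rmsd_buried=(sidechain_rmsd(model, native, "buried")
                     if "buried" in burial.values() else None),
        rmsd_exposed=(sidechain_rmsd(model, native, "exposed")
                      if "exposed" in burial.values() else None),
        chi1_pct=chi1, chi12_pct=chi12,
        nrmsd=nrmsd(model, native, library) if library is not None else {},
        contact_score=contact_score(model, native),
        burial=burial)
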