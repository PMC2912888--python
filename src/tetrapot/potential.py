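"""The four-term knowledge-based potential.

E = w_scsc * E_ScSc + w_scmc * E_ScMc + w_rot * E_rot + w_lj * (E_lja + E_ljr)

* E_ScSc / E_ScMc: inverse-Boltzmann log-ratio of the observed four-distance
  contact probability against the randomized-rotamer reference,
  -sum ln[(P_real({dist}|AA) P_real(AA)) / (P_rand({dist}|AA) P_rand(AA))]
  over unique contacting residue pairs. Lower is better; the natural log is
  used and any temperature factor is absorbed into the weights.
* E_rot: -sum ln(N_i p_i) over assigned residues — zero for a uniform group,
  negative for above-uniform rotamer probability.
* E_lj: 12-6 Lennard-Jones over classified heavy-atom pairs, with the
  repulsive branch replaced by its tangent line below d = 0.89 r_min;
  attractive contributions accumulate in e_lja (<= 0), repulsive in
  e_ljr (>= 0).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contact_statistics import (DEFAULT_CUTOFF, PotentialTables,
                                 extract_contacts)
from .errors import ParameterError
from .rotamer_library import Rotamer, RotamerLibrary
from .structure_model import UNCLASSIFIED, LJParams, Structure

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Weights:
    """Term weights; the defaults are the shipped calibration result."""

    w_scsc: float = 0.13
    w_scmc: float = 0.13
    w_rot: float = 0.33
    w_lj: float = 0.41

    def __post_init__(self) -> None:
        for v in (self.w_scsc, self.w_scmc, self.w_rot, self.w_lj):
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError("weights must be finite and non-negative")


DEFAULT_WEIGHTS = Weights()


@dataclass
class EnergyBreakdown:
    """Per-term scores and the weighted total."""

    e_scsc: float = 0.0
    e_scmc: float = 0.0
    e_rot: float = 0.0
    e_lja: float = 0.0
    e_ljr: float = 0.0
    weights: Weights = field(default_factory=Weights)
    counts: dict = field(default_factory=dict)

    @property
    def e_lj(self) -> float:
        return self.e_lja + self.e_ljr

    @property
    def total(self) -> float:
        w = self.weights
        return (w.w_scsc * self.e_scsc + w.w_scmc * self.e_scmc
                + w.w_rot * self.e_rot + w.w_lj * self.e_lj)


def _log_ratio_sum(contacts, tables: PotentialTables) -> tuple[float, int]:
    score = 0.0
    n = 0
    warned: set = set()
    for c in contacts:
        key = c.pair_key
        hr = tables.real.get(key)
        hq = tables.random.get(key)
        if hr is None or hq is None or hr.uninformative:
            if key not in warned:
                log.warning("pair %s not covered by tables; contributes 0", key)
                warned.add(key)
            continue
        floor = tables.floor_for(key)
        idx = hr.bin_index(c.quadruple)
        pr = max(float(hr.probabilities[idx]), floor)
        pq = max(float(hq.probabilities[idx]), floor)
        fr = max(tables.pair_frequency_real.get(key, 0.0), floor)
        fq = max(tables.pair_frequency_random.get(key, 0.0), floor)
        score -= math.log((pr * fr) / (pq * fq))
        n += 1
    return score, n


def score_scsc(structure: Structure, tables: PotentialTables,
               cutoff: float = DEFAULT_CUTOFF) -> tuple[float, int]:
    """Side chain-side chain term over unique contacting residue pairs."""
    defs = {k: v for k, v in tables.definitions.items() if not v.is_scmc}
    contacts = extract_contacts(structure, defs, cutoff)
    return _log_ratio_sum(contacts, tables)


def score_scmc(structure: Structure, tables: PotentialTables,
               cutoff: float = DEFAULT_CUTOFF) -> tuple[float, int]:
    """Side chain-main chain term (backbone represented by its (O, N) pair)."""
    defs = {k: v for k, v in tables.definitions.items() if v.is_scmc}
    contacts = extract_contacts(structure, defs, cutoff)
    return _log_ratio_sum(contacts, tables)


def rotamer_log_term(rotamer: Rotamer, group: list[Rotamer]) -> float:
    """-ln(N p) for one residue; p resolved against the rotamer's group."""
    n = len(group)
    if rotamer.origin is not None:
        if not (0 <= rotamer.origin < n):
            raise ParameterError("rotamer origin index outside its group")
        p = group[rotamer.origin].probability
    else:
        matches = [r for r in group if r == rotamer]
        if not matches:
            raise ParameterError(
                f"rotamer {rotamer.chi} not found in its library group")
        p = matches[0].probability
    if p <= 0:
        raise ParameterError("zero-probability rotamer")
    return -math.log(n * p)


def score_rot(structure: Structure, assignment: dict[int, Rotamer],
              library: RotamerLibrary) -> float:
    """Rotamer term: -sum ln(N_i p_i) over the assigned residues."""
    total = 0.0
    for i, rot in assignment.items():
        res = structure.residues[i]
        group = library.group(res.type, res.phi, res.psi)
        total += rotamer_log_term(rot, group)
    return total


def lj_pair_energy(d: np.ndarray, eps: np.ndarray, rmin: np.ndarray,
                   linearization_ratio: float = 0.89) -> np.ndarray:
    """12-6 energy with tangent-line continuation below ratio * r_min."""
    d = np.asarray(d, float)
    x = rmin / d
    e = eps * (x ** 12 - 2.0 * x ** 6)
    d0 = linearization_ratio * rmin
    x0 = 1.0 / linearization_ratio
    e0 = eps * (x0 ** 12 - 2.0 * x0 ** 6)
    # de/dd at d0: eps * (-12 rmin^12/d^13 + 12 rmin^6/d^7)
    slope = eps * 12.0 * (x0 ** 6 - x0 ** 12) / d0
    lin = e0 + slope * (d - d0)
    return np.where(d < d0, lin, e)


def _lj_exclusion_mask(structure: Structure, res_idx: np.ndarray,
                       is_bb: np.ndarray, names: np.ndarray,
                       ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    """True where the pair must be skipped: same residue, backbone-backbone,
    or within 3 covalent bonds across the peptide link."""
    same = res_idx[ii] == res_idx[jj]
    bbbb = is_bb[ii] & is_bb[jj]
    mask = same | bbbb
    # 1-4 side-chain exclusions across the peptide bond: CB(i)-N(i+1) and
    # C(i)-CB(i+1); Pro's CD/CG reach back to the preceding carbonyl.
    adj = np.abs(res_idx[ii] - res_idx[jj]) == 1
    cand = np.where(adj & ~mask)[0]
    residues = structure.residues
    for k in cand:
        a, b = ii[k], jj[k]
        if res_idx[a] > res_idx[b]:
            a, b = b, a
        ra, rb = residues[res_idx[a]], residues[res_idx[b]]
        if ra.chain_id != rb.chain_id:
            continue
        na, nb = names[a], names[b]
        if (na, nb) in (("CB", "N"), ("C", "CB")):
            mask[k] = True
        elif rb.type == "PRO" and (
                (na in ("C", "O", "CA") and nb == "CD")
                or (na == "C" and nb == "CG")):
            mask[k] = True
    return mask


def score_lj(structure: Structure, params: LJParams) -> tuple[float, float]:
    """Lennard-Jones packing term: (e_lja, e_ljr).

    Atoms must be classified (assign_lj_classes); unclassified atoms are
    skipped. Pairs beyond ``params.cutoff`` (default 10 A) are ignored.
    """
    coords, classes, res_idx, is_bb, names = _atom_arrays(structure)
    ok = classes != UNCLASSIFIED
    if not ok.all():
        log.info("score_lj: skipping %d unclassified atoms", int((~ok).sum()))
    idx = np.where(ok)[0]
    if len(idx) < 2:
        return 0.0, 0.0
    tree = cKDTree(coords[idx])
    pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0, 0.0
    ii, jj = idx[pairs[:, 0]], idx[pairs[:, 1]]
    excl = _lj_exclusion_mask(structure, res_idx, is_bb, names, ii, jj)
    ii, jj = ii[~excl], jj[~excl]
    if len(ii) == 0:
        return 0.0, 0.0
    d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
    eps = np.empty(len(ii))
    rmin = np.empty(len(ii))
    for k in range(len(ii)):
        ci, cj = classes[ii[k]], classes[jj[k]]
        eps[k] = params.eps_ij(ci, cj)
        rmin[k] = params.rmin_ij(ci, cj)
    e = lj_pair_energy(d, eps, rmin, params.linearization_ratio)
    return float(e[e < 0].sum()), float(e[e > 0].sum())


def _atom_arrays(structure: Structure):
    coords, classes, res_idx, is_bb, names = [], [], [], [], []
    for i, res, a in structure.all_atoms():
        coords.append(a.coords)
        classes.append(a.lj_class if a.lj_class is not None else UNCLASSIFIED)
        res_idx.append(i)
        is_bb.append(a.is_backbone)
        names.append(a.name)
    return (np.array(coords), np.array(classes), np.array(res_idx),
            np.array(is_bb), np.array(names))


def total_score(structure: Structure, tables: PotentialTables,
                library: RotamerLibrary | None, params: LJParams,
                weights: Weights = DEFAULT_WEIGHTS,
                assignment: dict[int, Rotamer] | None = None,
                ) -> EnergyBreakdown:
    """Full weighted score. E_rot needs an explicit rotamer assignment and
    is reported as 0 (count 0) when none is given."""
    e_scsc, n_scsc = score_scsc(structure, tables)
    e_scmc, n_scmc = score_scmc(structure, tables)
    if assignment is not None and library is not None:
        e_rot = score_rot(structure, assignment, library)
        n_rot = len(assignment)
    else:
        e_rot, n_rot = 0.0, 0
    e_lja, e_ljr = score_lj(structure, params)
    return EnergyBreakdown(e_scsc=e_scsc, e_scmc=e_scmc, e_rot=e_rot,
                           e_lja=e_lja, e_ljr=e_ljr, weights=weights,
                           counts={"scsc": n_scsc, "scmc": n_scmc,
                                   "rot": n_rot})
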