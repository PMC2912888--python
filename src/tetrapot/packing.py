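"""Side-chain placement by Monte Carlo simulated annealing.

The packer starts from random rotamers, calibrates the starting temperature
upward until 95% of probe moves are accepted, cools linearly to zero over a
fixed number of steps with a fixed number of uniform (position, rotamer)
proposals per step, tracks the best-scoring assignment, and finishes with a
greedy quench (single-rotamer substitutions until a full pass brings no
improvement).

Scorers are pluggable: anything with ``total(assignment)`` (and optionally
``delta(assignment, pos, rot)`` and ``set_rotamer``) works; ``EnergyModel``
wires in the four-term potential with residue-local incremental updates.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import constants as C
from .contact_statistics import (DEFAULT_CUTOFF, PotentialTables)
from .errors import ParameterError, TetrapotError
from .potential import (EnergyBreakdown, Weights, lj_pair_energy,
                        rotamer_log_term, total_score)
from .rotamer_library import Rotamer, RotamerLibrary
from .sidechain_geometry import rebuild_side_chain
from .structure_model import UNCLASSIFIED, LJParams, Structure

log = logging.getLogger(__name__)


@dataclass
class MCSAConfig:
    cooling_steps: int = 100
    moves_per_step: int = 10000
    warmup_acceptance: float = 0.95
    rng_seed: int = 0
    off_rotamer: bool = False
    off_rotamer_delta: float = 5.0
    library_variant: str = "full"

    def __post_init__(self) -> None:
        if self.cooling_steps < 1:
            raise ParameterError("cooling_steps must be >= 1")
        if not (0.0 < self.warmup_acceptance < 1.0):
            raise ParameterError("warmup_acceptance must be in (0, 1)")


@dataclass
class PackingResult:
    assignment: dict[int, Rotamer]
    structure: Structure | None
    score: float
    breakdown: EnergyBreakdown | None
    trajectory: list[dict]
    seed: int


class EnergyModel:
    """Four-term scorer over a working copy of a structure.

    ``delta`` recomputes only the moved residue's interactions (its rotamer
    term, its ScSc/ScMc contacts and LJ pairs involving its side chain), so
    a move costs O(neighbourhood) instead of a full rescore.
    """

    def __init__(self, structure: Structure, tables: PotentialTables,
                 library: RotamerLibrary, params: LJParams,
                 weights: Weights = Weights()):
        self.structure = structure.copy()
        self.tables = tables
        self.library = library
        self.params = params
        self.weights = weights
        self.groups: dict[int, list[Rotamer]] = {}
        for i, res in enumerate(self.structure.residues):
            if C.N_CHI[res.type] == 0:
                if res.type == "ALA" and res.coords_of(("N", "CA", "C")) is not None:
                    rebuild_side_chain(res, [])
                continue
            if res.coords_of(("N", "CA", "C")) is None:
                log.warning("residue %d lacks backbone; frozen", i)
                continue
            try:
                self.groups[i] = library.group(res.type, res.phi, res.psi)
            except KeyError:
                log.warning("no rotamers for %s; frozen", res.type)

    @property
    def positions(self) -> list[int]:
        return sorted(self.groups)

    def set_rotamer(self, pos: int, rot: Rotamer) -> None:
        rebuild_side_chain(self.structure.residues[pos], rot.chi)

    def apply(self, assignment: dict[int, Rotamer]) -> None:
        for pos, rot in assignment.items():
            self.set_rotamer(pos, rot)

    def total(self, assignment: dict[int, Rotamer]) -> float:
        self.apply(assignment)
        return self.breakdown(assignment).total

    def breakdown(self, assignment: dict[int, Rotamer]) -> EnergyBreakdown:
        return total_score(self.structure, self.tables, self.library,
                           self.params, self.weights, assignment)

    def delta(self, assignment: dict[int, Rotamer], pos: int,
              rot: Rotamer) -> float:
        """Energy change of substituting ``rot`` at ``pos`` (state restored)."""
        old_rot = assignment[pos]
        e_old = self._local_energy(pos, old_rot)
        self.set_rotamer(pos, rot)
        e_new = self._local_energy(pos, rot)
        self.set_rotamer(pos, old_rot)
        return e_new - e_old

    # -- residue-local terms ------------------------------------------------

    def _local_energy(self, pos: int, rot: Rotamer) -> float:
        w = self.weights
        e = w.w_rot * rotamer_log_term(rot, self.groups[pos])
        e += w.w_scsc * self._local_scsc(pos)
        e += w.w_scmc * self._local_scmc(pos)
        e += w.w_lj * self._local_lj(pos)
        return e

    def _pair_term(self, key, quad) -> float:
        t = self.tables
        hr, hq = t.real.get(key), t.random.get(key)
        if hr is None or hq is None or hr.uninformative:
            return 0.0
        floor = t.floor_for(key)
        idx = hr.bin_index(quad)
        pr = max(float(hr.probabilities[idx]), floor)
        pq = max(float(hq.probabilities[idx]), floor)
        fr = max(t.pair_frequency_real.get(key, 0.0), floor)
        fq = max(t.pair_frequency_random.get(key, 0.0), floor)
        return -math.log((pr * fr) / (pq * fq))

    def _local_scsc(self, pos: int) -> float:
        from .contact_statistics import _contact_distances
        res = self.structure.residues
        ri = res[pos]
        out = 0.0
        for j, rj in enumerate(res):
            if j == pos:
                continue
            if ri.chain_id == rj.chain_id and abs(j - pos) <= 1:
                continue
            t1, t2 = ri.type, rj.type
            key = (t1, t2) if t1 <= t2 else (t2, t1)
            d = self.tables.definitions.get(key)
            if d is None or d.is_scmc:
                continue
            a, b = (ri, rj) if t1 <= t2 else (rj, ri)
            dq = _contact_distances(a, b, d)
            if dq is not None and min(dq) < DEFAULT_CUTOFF:
                out += self._pair_term(key, dq)
            elif t1 == t2:
                dq2 = _contact_distances(b, a, d)
                if dq2 is not None and min(dq2) < DEFAULT_CUTOFF:
                    out += self._pair_term(key, dq2)
        return out

    def _local_scmc(self, pos: int) -> float:
        from .contact_statistics import MAINCHAIN, _contact_distances
        res = self.structure.residues
        ri = res[pos]
        key = (ri.type, MAINCHAIN)
        d = self.tables.definitions.get(key)
        if d is None:
            return 0.0
        out = 0.0
        for j, rj in enumerate(res):
            if j == pos:
                continue
            if ri.chain_id == rj.chain_id and abs(j - pos) <= 1:
                continue
            dq = _contact_distances(ri, rj, d)
            if dq is not None and min(dq) < DEFAULT_CUTOFF:
                out += self._pair_term(key, dq)
        return out

    def _local_lj(self, pos: int) -> float:
        res = self.structure.residues
        ri = res[pos]
        sc = [a for a in ri.side_chain_atoms
              if a.lj_class not in (None, UNCLASSIFIED)]
        if not sc:
            return 0.0
        total = 0.0
        p = self.params
        for j, rj in enumerate(res):
            if j == pos:
                continue
            adjacent = (ri.chain_id == rj.chain_id and abs(j - pos) == 1)
            for b in rj.atoms:
                if b.lj_class in (None, UNCLASSIFIED):
                    continue
                for a in sc:
                    if adjacent and _peptide_excluded(ri, a, rj, b, pos < j):
                        continue
                    d = float(np.linalg.norm(a.coords - b.coords))
                    if d >= p.cutoff:
                        continue
                    total += float(lj_pair_energy(
                        d, p.eps_ij(a.lj_class, b.lj_class),
                        p.rmin_ij(a.lj_class, b.lj_class),
                        p.linearization_ratio))
        return total


def _peptide_excluded(ri, a, rj, b, i_before_j: bool) -> bool:
    """Same 1-3/1-4 peptide-bond exclusions as the full LJ scorer, seen from
    the side-chain atom ``a`` of residue ``ri``."""
    if i_before_j:
        if a.name == "CB" and b.name == "N":
            return True
        if rj.type == "PRO" and a.name in ("C", "O", "CA"):
            return False  # a is side chain here, cannot match
    else:
        if a.name == "CB" and b.name == "C":
            return True
        if ri.type == "PRO" and b.name == "C" and a.name in ("CD", "CG"):
            return True
        if ri.type == "PRO" and b.name in ("O", "CA") and a.name == "CD":
            return True
    return False


# -- generic scorer adapters ------------------------------------------------

def _total(scorer, assignment) -> float:
    if hasattr(scorer, "total"):
        return scorer.total(assignment)
    return scorer(assignment)


def _delta(scorer, assignment, pos, rot) -> float:
    if hasattr(scorer, "delta"):
        return scorer.delta(assignment, pos, rot)
    old = assignment[pos]
    before = _total(scorer, assignment)
    assignment[pos] = rot
    after = _total(scorer, assignment)
    assignment[pos] = old
    return after - before


def _mutable_positions(structure: Structure, library: RotamerLibrary
                       ) -> dict[int, list[Rotamer]]:
    groups = {}
    for i, res in enumerate(structure.residues):
        if C.N_CHI[res.type] == 0:
            continue
        if res.coords_of(("N", "CA", "C")) is None:
            continue
        try:
            groups[i] = library.group(res.type, res.phi, res.psi)
        except KeyError:
            continue
    return groups


def calibrate_temperature(scorer, structure: Structure,
                          library: RotamerLibrary,
                          rng: np.random.Generator,
                          assignment: dict[int, Rotamer] | None = None,
                          target: float = 0.95, n_probe: int = 1000,
                          max_doublings: int = 60) -> float:
    """Double T from 1 until >= ``target`` of probe moves would be accepted.

    Probe moves are hypothetical: the working assignment is never changed."""
    groups = _mutable_positions(structure, library)
    if not groups:
        return 1.0
    if assignment is None:
        assignment = {}
        for i, g in sorted(groups.items()):
            k = int(rng.integers(len(g)))
            assignment[i] = replace(g[k], origin=k)
    positions = sorted(groups)
    T = 1.0
    for _ in range(max_doublings):
        accepted = 0
        for _ in range(n_probe):
            pos = positions[int(rng.integers(len(positions)))]
            g = groups[pos]
            k = int(rng.integers(len(g)))
            de = _delta(scorer, assignment, pos, replace(g[k], origin=k))
            if de <= 0 or rng.random() < math.exp(-de / T):
                accepted += 1
        if accepted / n_probe >= target:
            return T
        T *= 2.0
    raise TetrapotError(
        f"acceptance never reached {target} within {max_doublings} doublings")


def quench(structure: Structure, assignment: dict[int, Rotamer], scorer,
           library: RotamerLibrary) -> dict[int, Rotamer]:
    """Greedy single-rotamer descent to a 1-substitution-local optimum.

    Full passes over all positions; at each position every rotamer of the
    group is tested and an improving one is kept; stops when a whole pass
    improves nothing. The score trace is monotone non-increasing."""
    groups = _mutable_positions(structure, library)
    assignment = dict(assignment)
    if hasattr(scorer, "apply"):
        scorer.apply(assignment)
    improved = True
    while improved:
        improved = False
        for pos in sorted(groups):
            g = groups[pos]
            best_de = -1e-12
            best_rot = None
            for k, r in enumerate(g):
                cand = replace(r, origin=k)
                if cand == assignment[pos] and cand.origin == assignment[pos].origin:
                    continue
                de = _delta(scorer, assignment, pos, cand)
                if de < best_de:
                    best_de = de
                    best_rot = cand
            if best_rot is not None:
                assignment[pos] = best_rot
                if hasattr(scorer, "set_rotamer"):
                    scorer.set_rotamer(pos, best_rot)
                improved = True
    return assignment


def off_rotamer_step(assignment: dict[int, Rotamer], rng: np.random.Generator,
                     delta: float = 5.0) -> tuple[dict[int, Rotamer], int]:
    """Propose one +-delta-degree perturbation of one chi of one residue.

    Residues without rotatable chi never appear in the assignment. Returns
    the proposed assignment (a copy) and the perturbed position."""
    positions = sorted(assignment)
    pos = positions[int(rng.integers(len(positions)))]
    rot = assignment[pos]
    k = int(rng.integers(len(rot.chi)))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    chi = tuple(c + sign * delta if i == k else c
                for i, c in enumerate(rot.chi))
    new = dict(assignment)
    new[pos] = replace(rot, chi=chi)
    return new, pos


def mcsa_pack(structure: Structure, scorer, library: RotamerLibrary,
              config: MCSAConfig | None = None) -> PackingResult:
    """Simulated-annealing side-chain optimisation with final quench."""
    config = config or MCSAConfig()
    rng = np.random.default_rng(config.rng_seed)
    groups = _mutable_positions(structure, library)
    if not groups:
        score = _total(scorer, {}) if not hasattr(scorer, "breakdown") else \
            scorer.breakdown({}).total
        return PackingResult(assignment={}, structure=structure.copy(),
                             score=score, breakdown=None, trajectory=[],
                             seed=config.rng_seed)
    positions = sorted(groups)
    assignment = {}
    for i in positions:
        g = groups[i]
        k = int(rng.integers(len(g)))
        assignment[i] = replace(g[k], origin=k)
    current = _total(scorer, assignment)
    T0 = calibrate_temperature(scorer, structure, library, rng,
                               assignment=assignment,
                               target=config.warmup_acceptance)
    best = dict(assignment)
    best_score = current
    trajectory = []
    for step in range(config.cooling_steps):
        T = T0 * (1.0 - step / config.cooling_steps)
        accepted = 0
        for _ in range(config.moves_per_step):
            pos = positions[int(rng.integers(len(positions)))]
            g = groups[pos]
            k = int(rng.integers(len(g)))
            cand = replace(g[k], origin=k)
            de = _delta(scorer, assignment, pos, cand)
            accept = de < 0 or (T > 0 and de == 0) or (
                T > 0 and rng.random() < math.exp(-de / T))
            if accept:
                assignment[pos] = cand
                if hasattr(scorer, "set_rotamer"):
                    scorer.set_rotamer(pos, cand)
                current += de
                accepted += 1
                if current < best_score - 1e-12:
                    best_score = current
                    best = dict(assignment)
        if config.off_rotamer:
            proposal, pos = off_rotamer_step(assignment, rng,
                                             config.off_rotamer_delta)
            de = _delta(scorer, assignment, pos, proposal[pos])
            if de < 0 or (T > 0 and rng.random() < math.exp(-de / T)):
                assignment = proposal
                if hasattr(scorer, "set_rotamer"):
                    scorer.set_rotamer(pos, assignment[pos])
                current += de
                if current < best_score - 1e-12:
                    best_score = current
                    best = dict(assignment)
        trajectory.append({"step": step, "T": T, "current": current,
                           "best": best_score,
                           "acceptance": accepted / config.moves_per_step})
    assignment = quench(structure, best, scorer, library)
    final = _total(scorer, assignment)
    if final <= best_score + 1e-12:
        best, best_score = assignment, final
    out_structure = None
    breakdown = None
    if isinstance(scorer, EnergyModel):
        scorer.apply(best)
        out_structure = scorer.structure.copy()
        breakdown = scorer.breakdown(best)
        best_score = breakdown.total
    return PackingResult(assignment=best, structure=out_structure,
                         score=best_score, breakdown=breakdown,
                         trajectory=trajectory, seed=config.rng_seed)


def best_rotameric(native: Structure, library: RotamerLibrary) -> Structure:
    """Rebuild each side chain with its RMSD-closest library rotamer.

    The per-residue accuracy ceiling of rotamer-based packing: every residue
    independently gets the group rotamer minimising symmetry-aware heavy-atom
    RMSD to the native side chain (ties: lower library index)."""
    from .evaluation import residue_sidechain_rmsd
    out = native.copy()
    groups = _mutable_positions(out, library)
    for i, g in groups.items():
        res = out.residues[i]
        native_res = native.residues[i]
        expected = set(C.SIDE_CHAIN_ATOMS[res.type])
        present = {a.name for a in native_res.side_chain_atoms}
        if not expected <= present:
            log.warning("residue %d (%s) truncated in native; skipped", i, res.type)
            continue
        best_k, best_rmsd = None, None
        for k, rot in enumerate(g):
            rebuild_side_chain(res, rot.chi)
            r, _ = residue_sidechain_rmsd(res, native_res)
            if best_rmsd is None or r < best_rmsd - 1e-12:
                best_k, best_rmsd = k, r
        rebuild_side_chain(res, g[best_k].chi)
    return out
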