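"""Calibration: LJ radii from observed contact distances, term weights by a
hierarchical lambda sweep.

Radii: atoms in direct contact are collected (an occlusion-aware detector
with an enlarged 1 A probe), per-class-pair distance distributions are
built, and the 20 class radii are least-squares fitted so r_i + r_j
reproduces each distribution's peak. Polar-polar peaks are excluded from
the fit (hydrogen bonds are shorter than van der Waals contact) and kept as
explicit r_min overrides instead.

Weights: three sequential 21-point sweeps of E = lambda*A + (1-lambda)*B —
first E_rot against E_lj, then E_ScSc against their combination, finally
E_ScMc against the rest — minimising mean repacked side-chain RMSD on a
fixed training set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .contact_statistics import PotentialTables
from .errors import FitError, ParameterError
from .evaluation import sidechain_rmsd
from .packing import EnergyModel, MCSAConfig, mcsa_pack
from .potential import Weights
from .rotamer_library import RotamerLibrary
from .structure_model import UNCLASSIFIED, LJParams, Structure

log = logging.getLogger(__name__)

#: element van der Waals radii used only for direct-contact detection
_DETECT_VDW = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}

MIN_OBSERVATIONS = 10000


@dataclass
class DistanceDistribution:
    """Interatomic distance histogram for one LJ class pair."""

    class_pair: tuple[str, str]
    bin_size: float
    counts: np.ndarray
    edges: np.ndarray
    observation_count: int

    @property
    def insufficient(self) -> bool:
        return self.observation_count < MIN_OBSERVATIONS

    @property
    def peak(self) -> float:
        """Mode of the histogram after 3-bin moving-average smoothing.

        Ties in the smoothed profile (e.g. around a single sharp spike)
        break toward the bin with the largest raw count."""
        if self.observation_count == 0:
            raise FitError(f"empty distribution for {self.class_pair}")
        sm = np.convolve(self.counts, np.ones(3) / 3.0, mode="same")
        tied = np.flatnonzero(sm >= sm.max() - 1e-9)
        k = int(tied[np.argmax(self.counts[tied])])
        return float(0.5 * (self.edges[k] + self.edges[k + 1]))


def detect_direct_contacts(corpus: list[Structure],
                           probe_radius: float = 1.0,
                           ) -> list[tuple[tuple[str, str], float]]:
    """Atom pairs in direct contact across a corpus of classified structures.

    Two heavy atoms are in direct contact when their surface gap is below
    twice the probe radius and no third atom's sphere intersects the
    segment between their surfaces (occlusion test). Main chain-main chain
    pairs are included. Returns ((class_i, class_j), distance) records with
    the class pair sorted.
    """
    out = []
    for structure in corpus:
        atoms = [(i, r, a) for i, r, a in structure.all_atoms()
                 if a.lj_class not in (None, UNCLASSIFIED)]
        if len(atoms) < 2:
            continue
        coords = np.array([a.coords for _, _, a in atoms])
        vdw = np.array([_DETECT_VDW.get(a.element, 1.7) for _, _, a in atoms])
        res_idx = np.array([i for i, _, _ in atoms])
        tree = cKDTree(coords)
        cutoff = 2 * vdw.max() + 2 * probe_radius
        for a, b in sorted(tree.query_pairs(cutoff)):
            if res_idx[a] == res_idx[b]:
                continue
            d = float(np.linalg.norm(coords[a] - coords[b]))
            if d - (vdw[a] + vdw[b]) >= 2 * probe_radius:
                continue
            if _occluded(coords, vdw, a, b, tree):
                continue
            ca, cb = atoms[a][2].lj_class, atoms[b][2].lj_class
            pair = (ca, cb) if ca <= cb else (cb, ca)
            out.append((pair, d))
    return out


def _occluded(coords: np.ndarray, vdw: np.ndarray, a: int, b: int,
              tree: cKDTree) -> bool:
    pa, pb = coords[a], coords[b]
    axis = pb - pa
    L = np.linalg.norm(axis)
    u = axis / L
    s0, s1 = vdw[a], L - vdw[b]
    if s1 <= s0:
        return False  # surfaces interpenetrate; nothing can fit between
    mid = 0.5 * (pa + pb)
    for c in tree.query_ball_point(mid, L / 2 + vdw.max()):
        if c in (a, b):
            continue
        t = float(np.dot(coords[c] - pa, u))
        t = min(max(t, s0), s1)
        dist = float(np.linalg.norm(coords[c] - (pa + t * u)))
        if dist < vdw[c]:
            return True
    return False


def build_distance_distributions(
        contacts: list[tuple[tuple[str, str], float]],
        bin_size: float = 0.05, max_distance: float = 10.0,
        ) -> list[DistanceDistribution]:
    """Group contact distances by class pair into fine-binned histograms."""
    edges = np.arange(0.0, max_distance + bin_size / 2, bin_size)
    by_pair: dict[tuple[str, str], list[float]] = {}
    for pair, d in contacts:
        by_pair.setdefault(pair, []).append(d)
    out = []
    for pair, ds in sorted(by_pair.items()):
        counts, _ = np.histogram(ds, bins=edges)
        out.append(DistanceDistribution(class_pair=pair, bin_size=bin_size,
                                        counts=counts, edges=edges,
                                        observation_count=len(ds)))
    return out


def fit_lj_radii(distributions: list[DistanceDistribution],
                 polar: dict[str, bool],
                 min_observations: int = MIN_OBSERVATIONS,
                 ) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Least-squares fit of per-class radii to contact-distance peaks.

    Pairs with fewer than ``min_observations`` observations are discarded;
    polar-polar pairs are excluded from the residual vector and returned as
    r_min overrides. Returns (radii, overrides)."""
    retained = [d for d in distributions
                if d.observation_count >= min_observations]
    fit_rows = [d for d in retained
                if not (polar.get(d.class_pair[0], False)
                        and polar.get(d.class_pair[1], False))]
    overrides = {d.class_pair: d.peak for d in retained if d not in fit_rows}
    classes = sorted({c for d in fit_rows for c in d.class_pair})
    if not fit_rows:
        raise FitError("no retained non-polar-polar distributions")
    col = {c: k for k, c in enumerate(classes)}
    A = np.zeros((len(fit_rows), len(classes)))
    y = np.zeros(len(fit_rows))
    for r, d in enumerate(fit_rows):
        ci, cj = d.class_pair
        A[r, col[ci]] += 1.0
        A[r, col[cj]] += 1.0
        y[r] = d.peak
    for c in classes:
        if not A[:, col[c]].any():
            raise FitError(f"class {c} has no retained pair")
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return {c: float(sol[col[c]]) for c in classes}, overrides


def fit_weights(training: list[Structure], tables: PotentialTables,
                library: RotamerLibrary, params: LJParams,
                rng_seed: int = 0,
                lam_grid: np.ndarray | None = None,
                mcsa_config: MCSAConfig | None = None,
                objective=None) -> Weights:
    """Hierarchical lambda sweep for the four term weights.

    The objective (mean repacked side-chain RMSD over the training natives,
    evaluated with identical per-structure seeds at every lambda) can be
    overridden for testing via ``objective(weights) -> float``.
    """
    if lam_grid is None:
        lam_grid = np.round(np.arange(0.0, 1.0001, 0.05), 4)
    if len(lam_grid) == 0:
        raise ParameterError("empty lambda grid")
    if objective is None:
        if not training:
            raise ParameterError("no training structures")
        objective = _repack_objective(training, tables, library, params,
                                      rng_seed, mcsa_config)

    def sweep(make_weights) -> float:
        best_lam, best_val = None, None
        for lam in lam_grid:
            val = objective(make_weights(float(lam)))
            if best_val is None or val < best_val:
                best_lam, best_val = float(lam), val
        return best_lam

    lam1 = sweep(lambda l: Weights(0.0, 0.0, l, 1.0 - l))
    lam2 = sweep(lambda l: Weights(l, 0.0, (1 - l) * lam1, (1 - l) * (1 - lam1)))
    lam3 = sweep(lambda l: Weights((1 - l) * lam2, l,
                                   (1 - l) * (1 - lam2) * lam1,
                                   (1 - l) * (1 - lam2) * (1 - lam1)))
    return Weights((1 - lam3) * lam2, lam3,
                   (1 - lam3) * (1 - lam2) * lam1,
                   (1 - lam3) * (1 - lam2) * (1 - lam1))


def _repack_objective(training, tables, library, params, rng_seed,
                      mcsa_config):
    config = mcsa_config or MCSAConfig(cooling_steps=20, moves_per_step=500)

    def objective(weights: Weights) -> float:
        rmsds = []
        for idx, native in enumerate(training):
            model = EnergyModel(native, tables, library, params, weights)
            cfg = MCSAConfig(cooling_steps=config.cooling_steps,
                             moves_per_step=config.moves_per_step,
                             rng_seed=rng_seed + 7919 * idx,
                             off_rotamer=config.off_rotamer)
            try:
                result = mcsa_pack(native, model, library, cfg)
                rmsds.append(sidechain_rmsd(result.structure, native))
            except Exception as exc:
                log.warning("packing failed on %s: %s", native.id, exc)
        if not rmsds:
            raise FitError("packing failed on every training structure")
        return float(np.mean(rmsds))

    return objective
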