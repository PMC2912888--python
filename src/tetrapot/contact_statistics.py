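"""Four-distance contact statistics.

A residue-residue interaction is described by two atoms chosen in each
residue and the four inter-residue distances between them. Two residues are
in contact when at least one of the four distances is below the cutoff
(default 5 A, strict). Contacts harvested from a corpus populate
four-dimensional histograms (0.5 A bins, 0-10 A per axis); a matching
reference ("random") distribution is harvested from copies of the corpus
whose side chains are replaced by uniformly drawn rotamers.

Side chain-main chain (ScMc) interactions reuse the machinery with the
backbone (O, N) pair standing in for the second residue's atom pair.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import constants as C
from .errors import ParameterError
from .rotamer_library import RotamerLibrary
from .sidechain_geometry import rebuild_side_chain
from .structure_model import Residue, Structure

log = logging.getLogger(__name__)

MAINCHAIN = "MAINCHAIN"
#: backbone atoms representing the main chain in ScMc interactions
SCMC_BACKBONE_PAIR = ("O", "N")
DEFAULT_CUTOFF = 5.0

# residues whose side chains can never extend beyond this from CA (Arg ~7.5)
_NEIGHBOUR_RADIUS_PAD = 16.0

PairKey = tuple[str, str]


@dataclass(frozen=True)
class AtomPairDefinition:
    """The four atoms describing one residue-pair interaction type.

    ``pair`` is alphabetically ordered for ScSc, or (residue type, MAINCHAIN)
    for ScMc; ``atoms_a`` belong to ``pair[0]`` and ``atoms_b`` to ``pair[1]``.
    """

    pair: PairKey
    atoms_a: tuple[str, str]
    atoms_b: tuple[str, str]

    @property
    def is_scmc(self) -> bool:
        return self.pair[1] == MAINCHAIN


@dataclass(frozen=True)
class FourDistanceContact:
    """One observed contact: d[i][j] = dist(atom i of res 1, atom j of res 2)."""

    pair_key: PairKey
    d11: float
    d12: float
    d21: float
    d22: float

    @property
    def quadruple(self) -> tuple[float, float, float, float]:
        return (self.d11, self.d12, self.d21, self.d22)

    def swapped(self) -> "FourDistanceContact":
        """The same contact with the two residues' roles exchanged."""
        return FourDistanceContact(self.pair_key, self.d11, self.d21,
                                   self.d12, self.d22)


@dataclass
class Histogram4D:
    """Binned 4-distance distribution for one interaction type."""

    pair_key: PairKey
    bin_size: float
    max_distance: float
    counts: np.ndarray
    probabilities: np.ndarray
    total_count: int
    smoothed: bool = False

    @property
    def n_bins(self) -> int:
        return int(round(self.max_distance / self.bin_size))

    @property
    def uninformative(self) -> bool:
        return self.total_count == 0

    def bin_index(self, quadruple: Sequence[float]) -> tuple[int, ...]:
        n = self.n_bins
        return tuple(min(int(d / self.bin_size), n - 1) for d in quadruple)


@dataclass
class PotentialTables:
    """Real and reference histograms plus pair-type frequencies.

    ``floor_probability``: constant probability floor applied before the
    log-ratio; None means the count-scaled default 1/(10 * total real count
    of the pair) is used at scoring time.
    """

    real: dict[PairKey, Histogram4D]
    random: dict[PairKey, Histogram4D]
    pair_frequency_real: dict[PairKey, float]
    pair_frequency_random: dict[PairKey, float]
    definitions: dict[PairKey, AtomPairDefinition]
    floor_probability: float | None = None
    provenance: dict = field(default_factory=dict)

    def floor_for(self, key: PairKey) -> float:
        if self.floor_probability is not None:
            return self.floor_probability
        total = self.real[key].total_count
        return 1.0 / (10.0 * max(total, 1))


def _pair_choices(res_type: str) -> list[tuple[str, str]]:
    """All unordered 2-atom choices within one residue's side chain.

    Ala has a single side-chain heavy atom, so its pair is (CA, CB) — this
    keeps Ala-containing interaction types definable (190 ScSc types with
    only Gly excluded). Gly yields no choices.
    """
    sc = C.SIDE_CHAIN_ATOMS[res_type]
    if res_type == "GLY":
        return []
    if res_type == "ALA":
        return [("CA", "CB")]
    return [tuple(sorted(p)) for p in itertools.combinations(sorted(sc), 2)]


def enumerate_candidates(type_a: str, type_b: str
                         ) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """All candidate 4-atom combinations for a residue-type pair.

    For a homotypic pair the same atom choice is used on both residues
    (symmetric definitions), so the candidates are the per-residue choices."""
    ca, cb = _pair_choices(type_a), _pair_choices(type_b)
    if not ca or not cb:
        return []
    if type_a == type_b:
        return [(p, p) for p in ca]
    return [(pa, pb) for pa in ca for pb in cb]


def scsc_pair_keys() -> list[PairKey]:
    """The residue-type pairs with a defined ScSc interaction (Gly excluded)."""
    types = [t for t in C.AMINO_ACIDS if t != "GLY"]
    return [tuple(sorted(p)) for p in
            itertools.combinations_with_replacement(types, 2)]


def scmc_pair_keys() -> list[PairKey]:
    """ScMc interaction types: side chains with >= 2 atoms (no Gly, no Ala)."""
    return [(t, MAINCHAIN) for t in C.AMINO_ACIDS if t not in ("GLY", "ALA")]


def default_scmc_definitions(scsc_defs: Mapping[PairKey, AtomPairDefinition]
                             | None = None) -> dict[PairKey, AtomPairDefinition]:
    """ScMc definitions: per residue, its side-chain pair against backbone (O, N).

    If ScSc definitions are given, the residue's atom pair is taken from its
    homotypic ScSc definition when available; otherwise the lexicographically
    first candidate pair is used.
    """
    out = {}
    for key in scmc_pair_keys():
        rt = key[0]
        atoms = None
        if scsc_defs is not None:
            homo = scsc_defs.get((rt, rt))
            if homo is not None:
                atoms = homo.atoms_a
        if atoms is None:
            atoms = _pair_choices(rt)[0]
        out[key] = AtomPairDefinition(pair=key, atoms_a=atoms,
                                      atoms_b=SCMC_BACKBONE_PAIR)
    return out


def _residue_neighbour_pairs(structure: Structure, radius: float
                             ) -> Iterable[tuple[int, int]]:
    """Candidate residue index pairs (i < j) within a generous CA radius,
    excluding same-chain sequence neighbours (|i - j| <= 1)."""
    res = structure.residues
    centers = []
    idx = []
    for i, r in enumerate(res):
        ca = r.atom("CA")
        if ca is not None:
            centers.append(ca.coords)
            idx.append(i)
    if not centers:
        return
    tree = cKDTree(np.array(centers))
    for a, b in sorted(tree.query_pairs(radius)):
        i, j = idx[a], idx[b]
        if res[i].chain_id == res[j].chain_id and abs(i - j) <= 1:
            continue
        yield (i, j) if i < j else (j, i)


def _contact_distances(r1: Residue, r2: Residue, d: AtomPairDefinition
                       ) -> tuple[float, float, float, float] | None:
    """The four distances for a residue pair already ordered to match ``d``."""
    pa = r1.coords_of(d.atoms_a)
    pb = r2.coords_of(d.atoms_b)
    if pa is None or pb is None:
        return None
    diff = pa[:, None, :] - pb[None, :, :]
    dm = np.sqrt((diff ** 2).sum(-1))
    return (float(dm[0, 0]), float(dm[0, 1]), float(dm[1, 0]), float(dm[1, 1]))


def select_atom_pairs(corpus: Sequence[Structure],
                      cutoff: float = DEFAULT_CUTOFF,
                      ) -> dict[PairKey, AtomPairDefinition]:
    """Choose, per residue-type pair, the atom combination with the most
    contacts across the corpus ("Atom Set 1" selection).

    Ties break toward lexicographically smaller atom names; type pairs with
    zero contacts anywhere are omitted with a warning.
    """
    if not corpus:
        raise ParameterError("empty corpus")
    counts: dict[PairKey, dict[tuple, int]] = {}
    for structure in corpus:
        res = structure.residues
        for i, j in _residue_neighbour_pairs(structure, cutoff + _NEIGHBOUR_RADIUS_PAD):
            r1, r2 = res[i], res[j]
            t1, t2 = r1.type, r2.type
            if t1 > t2:
                r1, r2 = r2, r1
                t1, t2 = t2, t1
            cands = enumerate_candidates(t1, t2)
            if not cands:
                continue
            key = (t1, t2)
            bucket = counts.setdefault(key, {})
            for pa, pb in cands:
                dq = _contact_distances(
                    r1, r2, AtomPairDefinition(key, pa, pb))
                if dq is None:
                    continue
                hit = min(dq) < cutoff
                if t1 == t2:
                    dq2 = _contact_distances(
                        r2, r1, AtomPairDefinition(key, pa, pb))
                    hit = hit or (dq2 is not None and min(dq2) < cutoff)
                if hit:
                    bucket[(pa, pb)] = bucket.get((pa, pb), 0) + 1
    out: dict[PairKey, AtomPairDefinition] = {}
    for key, bucket in counts.items():
        if not bucket:
            log.warning("select_atom_pairs: no contacts for %s; omitted", key)
            continue
        best = min(bucket.items(), key=lambda kv: (-kv[1], kv[0]))
        pa, pb = best[0]
        out[key] = AtomPairDefinition(pair=key, atoms_a=pa, atoms_b=pb)
    return out


def extract_contacts(structure: Structure,
                     defs: Mapping[PairKey, AtomPairDefinition],
                     cutoff: float = DEFAULT_CUTOFF,
                     ) -> list[FourDistanceContact]:
    """All four-distance contacts in a structure under the given definitions.

    One record per unique contacting residue pair per definition; same-chain
    sequence neighbours are excluded; homotypic pairs are canonically ordered
    by (chain id, residue index). ScMc definitions in ``defs`` are evaluated
    against every other residue's backbone.
    """
    out: list[FourDistanceContact] = []
    res = structure.residues
    scmc_defs = {k: v for k, v in defs.items() if v.is_scmc}
    for i, j in _residue_neighbour_pairs(structure, cutoff + _NEIGHBOUR_RADIUS_PAD):
        r1, r2 = res[i], res[j]
        t1, t2 = r1.type, r2.type
        # ScSc
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        d = defs.get(key)
        if d is not None and not d.is_scmc:
            a, b = (r1, r2) if t1 <= t2 else (r2, r1)
            dq = _contact_distances(a, b, d)
            if dq is None:
                log.debug("missing contact atoms for %s %s%d/%s%d", key,
                          r1.chain_id, r1.seq_id, r2.chain_id, r2.seq_id)
            elif min(dq) < cutoff:
                out.append(FourDistanceContact(key, *dq))
            elif t1 == t2:
                dq2 = _contact_distances(b, a, d)
                if dq2 is not None and min(dq2) < cutoff:
                    out.append(FourDistanceContact(key, *dq2))
        # ScMc: side chain of each residue against the other's backbone
        for sc_res, mc_res in ((r1, r2), (r2, r1)):
            mkey = (sc_res.type, MAINCHAIN)
            md = scmc_defs.get(mkey)
            if md is None:
                continue
            dq = _contact_distances(sc_res, mc_res, md)
            if dq is not None and min(dq) < cutoff:
                out.append(FourDistanceContact(mkey, *dq))
    return out


def build_histogram(contacts: Iterable[FourDistanceContact],
                    bin_size: float = 0.5, max_distance: float = 10.0,
                    pair_key: PairKey | None = None) -> Histogram4D:
    """Bin contact quadruples on a regular 4-D grid.

    Distances beyond ``max_distance`` are clamped into the last bin (a
    contact is never dropped for a long non-triggering distance)."""
    n = max_distance / bin_size
    if abs(n - round(n)) > 1e-9:
        raise ParameterError("bin_size must divide max_distance")
    n = int(round(n))
    counts = np.zeros((n, n, n, n), dtype=np.int64)
    key = pair_key
    total = 0
    for c in contacts:
        if key is None:
            key = c.pair_key
        idx = tuple(min(int(d / bin_size), n - 1) for d in c.quadruple)
        counts[idx] += 1
        total += 1
    probs = counts / total if total > 0 else counts.astype(float)
    return Histogram4D(pair_key=key if key is not None else ("?", "?"),
                       bin_size=bin_size, max_distance=max_distance,
                       counts=counts, probabilities=probs, total_count=total)


def _smoothing_kernel(ndim: int = 4) -> np.ndarray:
    """Axis-adjacent (von Neumann) averaging kernel: the bin itself plus its
    2*ndim face neighbours."""
    k = np.zeros((3,) * ndim)
    center = (1,) * ndim
    k[center] = 1.0
    for ax in range(ndim):
        for step in (0, 2):
            idx = list(center)
            idx[ax] = step
            k[tuple(idx)] = 1.0
    return k


def smooth_histogram(hist: Histogram4D) -> Histogram4D:
    """Average each bin with its axis-adjacent neighbours and itself.

    The neighbourhood (a 4-D cross of up to 9 bins) truncates at the grid
    boundary, so boundary bins average over fewer neighbours; the result is
    renormalised to unit mass. The cross-shaped neighbourhood preserves the
    location of an isolated peak, which a full-hypercube box average does
    not (it ties every window containing the peak)."""
    if hist.smoothed:
        raise ParameterError("histogram is already smoothed")
    p = hist.probabilities
    kernel = _smoothing_kernel(p.ndim)
    kernel_sum = ndimage.convolve(p, kernel, mode="constant", cval=0.0)
    neigh = ndimage.convolve(np.ones_like(p), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        sm = kernel_sum / neigh
    total = sm.sum()
    if total > 0:
        sm = sm / total
    return Histogram4D(pair_key=hist.pair_key, bin_size=hist.bin_size,
                       max_distance=hist.max_distance, counts=hist.counts,
                       probabilities=sm, total_count=hist.total_count,
                       smoothed=True)


def randomize_side_chains(structure: Structure, library: RotamerLibrary,
                          rng_seed: int = 0) -> Structure:
    """Rebuild every side chain from a uniformly drawn library rotamer.

    Rotamer probabilities are ignored and clashes are not checked — this is
    the reference-state construction. Backbone coordinates are untouched;
    Gly is skipped and Ala's CB is rebuilt from backbone geometry.
    """
    rng = np.random.default_rng(rng_seed)
    out = structure.copy()
    for r in out.residues:
        if r.type == "GLY":
            continue
        if C.N_CHI[r.type] == 0:  # ALA
            if r.coords_of(("N", "CA", "C")) is not None:
                rebuild_side_chain(r, [])
            continue
        try:
            group = library.group(r.type, r.phi, r.psi)
        except KeyError:
            log.warning("no rotamers for %s; side chain left as-is", r.type)
            continue
        rot = group[int(rng.integers(len(group)))]
        if r.coords_of(("N", "CA", "C")) is None:
            log.warning("missing backbone for %s%d; skipped", r.chain_id, r.seq_id)
            continue
        rebuild_side_chain(r, rot.chi)
    return out


def build_statistics(corpus: Sequence[Structure],
                     defs: Mapping[PairKey, AtomPairDefinition],
                     library: RotamerLibrary,
                     rng_seed: int = 0,
                     bin_size: float = 0.5,
                     max_distance: float = 10.0,
                     smooth: bool = True,
                     n_random: int = 1,
                     cutoff: float = DEFAULT_CUTOFF) -> PotentialTables:
    """Harvest real and randomized-reference statistics from a corpus."""
    if not corpus:
        raise ParameterError("empty corpus")

    def harvest(structures: Iterable[Structure]) -> dict[PairKey, list[FourDistanceContact]]:
        bucket: dict[PairKey, list[FourDistanceContact]] = {}
        for s in structures:
            for c in extract_contacts(s, defs, cutoff):
                bucket.setdefault(c.pair_key, []).append(c)
        return bucket

    real_contacts = harvest(corpus)
    randomized = []
    for i, s in enumerate(corpus):
        for k in range(n_random):
            randomized.append(
                randomize_side_chains(s, library, rng_seed + 1000003 * i + k))
    rand_contacts = harvest(randomized)

    def tables(bucket: dict[PairKey, list[FourDistanceContact]]
               ) -> tuple[dict[PairKey, Histogram4D], dict[PairKey, float]]:
        hists: dict[PairKey, Histogram4D] = {}
        freqs: dict[PairKey, float] = {}
        # frequencies normalised within family (ScSc vs ScMc)
        for family in (False, True):
            fam_keys = [k for k in defs if defs[k].is_scmc == family]
            fam_total = sum(len(bucket.get(k, [])) for k in fam_keys)
            for k in fam_keys:
                contacts = list(bucket.get(k, []))
                if k[0] == k[1]:  # homotypic: store swap-symmetric table
                    contacts = contacts + [c.swapped() for c in contacts]
                h = build_histogram(contacts, bin_size, max_distance, pair_key=k)
                if smooth and not h.uninformative:
                    h = smooth_histogram(h)
                hists[k] = h
                freqs[k] = (len(bucket.get(k, [])) / fam_total
                            if fam_total > 0 else 0.0)
        return hists, freqs

    real_h, real_f = tables(real_contacts)
    rand_h, rand_f = tables(rand_contacts)
    for k, h in real_h.items():
        if h.uninformative:
            log.warning("pair %s has no real contacts; flagged uninformative", k)
    prov = {"n_structures": len(corpus), "n_random": n_random,
            "bin_size": bin_size, "max_distance": max_distance,
            "smooth": smooth, "seed": rng_seed, "cutoff": cutoff,
            "corpus_ids": [s.id for s in corpus]}
    return PotentialTables(real=real_h, random=rand_h,
                           pair_frequency_real=real_f,
                           pair_frequency_random=rand_f,
                           definitions=dict(defs), provenance=prov)
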