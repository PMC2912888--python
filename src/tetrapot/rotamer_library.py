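"""Backbone-dependent rotamer libraries.

A library maps (residue type, phi bin, psi bin) to a list of discrete side
chain conformations (chi-angle tuples with per-angle spreads and a
probability within the group). Three variants exist:

* ``original`` — as loaded from the tabular text file;
* ``extended`` — every rotamer with n chi angles replaced by the 3**n
  combinations {chi - sigma, chi, chi + sigma}, probabilities redistributed
  by a discrete normal weight at the three offsets;
* ``reduced`` — low-probability rotamers discarded: within each group the
  largest probability-sorted tail whose cumulative probability does not
  exceed the threshold (default 0.03) is dropped and survivors renormalised.

File format (whitespace-separated, '#' comments)::

    residue  phi  psi  chi1 chi2 chi3 chi4  sig1 sig2 sig3 sig4  probability

with '-' in unused chi/sigma columns.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import constants as C
from .errors import FormatError, ParameterError
from .sidechain_geometry import build_side_chain_coords
from .structure_model import Residue

log = logging.getLogger(__name__)

GroupKey = tuple[str, int, int]


@dataclass(frozen=True)
class Rotamer:
    """One discrete side-chain conformation.

    ``origin`` optionally records the index of the parent rotamer within its
    library group; off-rotamer perturbed copies keep it so their library
    probability stays resolvable."""

    residue_type: str
    chi: tuple[float, ...]
    sigma: tuple[float, ...]
    probability: float
    origin: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.chi) != len(self.sigma):
            raise ValueError("chi/sigma length mismatch")
        if not (0.0 <= self.probability <= 1.0 + 1e-9):
            raise ValueError(f"probability {self.probability} outside [0,1]")


@dataclass
class RotamerLibrary:
    """Backbone-dependent rotamer sets on a phi/psi grid."""

    grid: float = 10.0
    entries: dict[GroupKey, list[Rotamer]] = field(default_factory=dict)
    variant: str = "original"

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.grid))

    def bin_of(self, angle: float) -> int:
        b = int(math.floor((angle + 180.0) / self.grid))
        return min(max(b, 0), self.n_bins - 1)

    def group(self, res_type: str, phi: float | None, psi: float | None
              ) -> list[Rotamer]:
        """Rotamer group for a residue at the given backbone dihedrals.

        Undefined phi/psi (chain termini) fall back to the nearest bin of a
        generic extended-region backbone (logged once per call site)."""
        if phi is None or psi is None:
            log.debug("undefined phi/psi for %s: using extended-region bin", res_type)
            phi = -120.0 if phi is None else phi
            psi = 130.0 if psi is None else psi
        key = (res_type, self.bin_of(phi), self.bin_of(psi))
        got = self.entries.get(key)
        if got is not None:
            return got
        # nearest populated bin for this residue type (circular distance)
        best, best_d = None, None
        for (rt, pb, sb), rots in self.entries.items():
            if rt != res_type:
                continue
            nb = self.n_bins
            dp = min(abs(pb - key[1]), nb - abs(pb - key[1]))
            ds = min(abs(sb - key[2]), nb - abs(sb - key[2]))
            d = dp * dp + ds * ds
            if best_d is None or d < best_d:
                best, best_d = rots, d
        if best is None:
            raise KeyError(f"no rotamers for residue type {res_type}")
        return best

    def residue_types(self) -> set[str]:
        return {k[0] for k in self.entries}


def _normalize_groups(entries: dict[GroupKey, list[Rotamer]],
                      check: bool = False) -> None:
    for key, rots in entries.items():
        total = sum(r.probability for r in rots)
        if total <= 0:
            raise FormatError(f"group {key} has zero total probability")
        if check and not (0.9 <= total <= 1.1):
            raise FormatError(
                f"group {key} probabilities sum to {total:.3f} (outside [0.9, 1.1])")
        if abs(total - 1.0) > 1e-9:
            if check:
                log.warning("group %s probabilities sum to %.3f; renormalising",
                            key, total)
            entries[key] = [Rotamer(r.residue_type, r.chi, r.sigma,
                                    r.probability / total) for r in rots]


def load_library(path: str | Path, grid: float = 10.0) -> RotamerLibrary:
    """Load a library from its tabular text format."""
    lib = RotamerLibrary(grid=grid)
    raw: dict[GroupKey, list[Rotamer]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 12:
            raise FormatError(f"line {ln}: expected 12 columns, got {len(parts)}")
        res = parts[0].upper()
        if res not in C.SIDE_CHAIN_ATOMS:
            raise FormatError(f"line {ln}: unknown residue type {res!r}")
        n_chi = C.N_CHI[res]
        phi, psi = float(parts[1]), float(parts[2])
        chi_cols, sig_cols = parts[3:7], parts[7:11]
        chi, sig = [], []
        for k in range(4):
            if k < n_chi:
                if chi_cols[k] == "-" or sig_cols[k] == "-":
                    raise FormatError(
                        f"line {ln}: {res} requires chi{k + 1}/sigma{k + 1}")
                chi.append(float(chi_cols[k]))
                sig.append(float(sig_cols[k]))
            elif chi_cols[k] != "-" or sig_cols[k] != "-":
                raise FormatError(f"line {ln}: {res} has no chi{k + 1}")
        prob = float(parts[11])
        key = (res, lib.bin_of(phi), lib.bin_of(psi))
        raw.setdefault(key, []).append(
            Rotamer(res, tuple(chi), tuple(sig), min(prob, 1.0)))
    if not raw:
        raise FormatError(f"no rotamer rows in {path}")
    _normalize_groups(raw, check=True)
    lib.entries = raw
    return lib


def save_library(lib: RotamerLibrary, path: str | Path) -> None:
    """Write a library back to the tabular text format."""
    lines = ["# residue phi psi chi1 chi2 chi3 chi4 sig1 sig2 sig3 sig4 probability"]
    for (res, pb, sb), rots in sorted(lib.entries.items()):
        phi = -180.0 + (pb + 0.5) * lib.grid
        psi = -180.0 + (sb + 0.5) * lib.grid
        for r in rots:
            chi = [f"{v:.2f}" for v in r.chi] + ["-"] * (4 - len(r.chi))
            sig = [f"{v:.2f}" for v in r.sigma] + ["-"] * (4 - len(r.sigma))
            lines.append(f"{res} {phi:.1f} {psi:.1f} " + " ".join(chi) + " "
                         + " ".join(sig) + f" {r.probability:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# discrete normal weights at offsets {-sigma, 0, +sigma}: density ratios
# exp(-1/2) : 1 : exp(-1/2), renormalised
_W_SIDE = math.exp(-0.5)
_W_NORM = 1.0 + 2.0 * _W_SIDE
EXTENSION_WEIGHTS = (_W_SIDE / _W_NORM, 1.0 / _W_NORM, _W_SIDE / _W_NORM)


def extend_library(lib: RotamerLibrary) -> RotamerLibrary:
    """Replace each n-chi rotamer by its 3**n one-sigma neighbours."""
    if lib.variant != "original":
        raise ParameterError(f"cannot extend a {lib.variant!r} library")
    out: dict[GroupKey, list[Rotamer]] = {}
    for key, rots in lib.entries.items():
        new: list[Rotamer] = []
        for r in rots:
            n = len(r.chi)
            if n == 0:
                new.append(r)
                continue
            for offsets in itertools.product((-1, 0, 1), repeat=n):
                chi = tuple(c + o * s for c, o, s in zip(r.chi, offsets, r.sigma))
                w = math.prod(EXTENSION_WEIGHTS[o + 1] for o in offsets)
                new.append(Rotamer(r.residue_type, chi, r.sigma,
                                   r.probability * w))
        out[key] = new
    _normalize_groups(out)
    return RotamerLibrary(grid=lib.grid, entries=out, variant="extended")


def reduce_library(lib: RotamerLibrary, tail: float = 0.03) -> RotamerLibrary:
    """Drop the lowest-probability tail of every group (cumulative <= tail)."""
    if not (0.0 <= tail < 1.0):
        raise ParameterError(f"tail must be in [0, 1), got {tail}")
    out: dict[GroupKey, list[Rotamer]] = {}
    for key, rots in lib.entries.items():
        ranked = sorted(rots, key=lambda r: (-r.probability, r.chi))
        cum = 0.0
        keep = len(ranked)
        for i in range(len(ranked) - 1, 0, -1):  # never drop the first
            cum += ranked[i].probability
            if cum <= tail + 1e-12:
                keep = i
            else:
                break
        out[key] = ranked[:keep]
    _normalize_groups(out)
    return RotamerLibrary(grid=lib.grid, entries=out, variant="reduced")


def build_side_chain(residue: Residue, rotamer: Rotamer,
                     geometry_table=None) -> dict[str, np.ndarray]:
    """Side-chain coordinates for ``residue``'s backbone at the rotamer's chi.

    Pure: does not modify the residue. Recomputing chi from the returned
    coordinates reproduces ``rotamer.chi`` to well under 0.01 degrees.
    """
    if rotamer.residue_type != residue.type:
        raise ParameterError(
            f"rotamer for {rotamer.residue_type} applied to {residue.type}")
    bb = {a.name: a.coords for a in residue.atoms if a.is_backbone}
    return build_side_chain_coords(bb, residue.type, rotamer.chi, geometry_table)
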