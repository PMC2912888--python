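"""HDF5 persistence for PotentialTables (bit-exact round trip).

Layout (version 1)::

    /meta                 attrs: format_version, floor_probability, provenance (JSON)
    /definitions          one row per pair: key, atoms
    /real/<pair>/counts   int64 grid      + attrs bin_size, max_distance, ...
    /real/<pair>/probabilities
    /random/<pair>/...
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .contact_statistics import (AtomPairDefinition, Histogram4D,
                                 PotentialTables)

FORMAT_VERSION = 1


def _key_str(key: tuple[str, str]) -> str:
    return f"{key[0]}__{key[1]}"


def _str_key(s: str) -> tuple[str, str]:
    a, b = s.split("__")
    return (a, b)


def save_tables(tables: PotentialTables, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["provenance"] = json.dumps(tables.provenance)
        meta.attrs["floor_probability"] = (
            -1.0 if tables.floor_probability is None else tables.floor_probability)
        dg = f.create_group("definitions")
        for key, d in tables.definitions.items():
            g = dg.create_group(_key_str(key))
            g.attrs["atoms_a"] = list(d.atoms_a)
            g.attrs["atoms_b"] = list(d.atoms_b)
        for name, hists, freqs in (("real", tables.real, tables.pair_frequency_real),
                                   ("random", tables.random, tables.pair_frequency_random)):
            root = f.create_group(name)
            for key, h in hists.items():
                g = root.create_group(_key_str(key))
                g.create_dataset("counts", data=h.counts, compression="gzip")
                g.create_dataset("probabilities", data=h.probabilities,
                                 compression="gzip")
                g.attrs["bin_size"] = h.bin_size
                g.attrs["max_distance"] = h.max_distance
                g.attrs["total_count"] = h.total_count
                g.attrs["smoothed"] = bool(h.smoothed)
                g.attrs["pair_frequency"] = freqs.get(key, 0.0)


def load_tables(path: str | Path) -> PotentialTables:
    with h5py.File(path, "r") as f:
        version = int(f["meta"].attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported tables format version {version}")
        floor = float(f["meta"].attrs["floor_probability"])
        prov = json.loads(f["meta"].attrs["provenance"])
        defs = {}
        for name, g in f["definitions"].items():
            key = _str_key(name)
            defs[key] = AtomPairDefinition(
                pair=key,
                atoms_a=tuple(str(a) for a in g.attrs["atoms_a"]),
                atoms_b=tuple(str(a) for a in g.attrs["atoms_b"]))
        out = {}
        freqs: dict[str, dict] = {"real": {}, "random": {}}
        for name in ("real", "random"):
            hists = {}
            for kstr, g in f[name].items():
                key = _str_key(kstr)
                hists[key] = Histogram4D(
                    pair_key=key,
                    bin_size=float(g.attrs["bin_size"]),
                    max_distance=float(g.attrs["max_distance"]),
                    counts=np.array(g["counts"]),
                    probabilities=np.array(g["probabilities"]),
                    total_count=int(g.attrs["total_count"]),
                    smoothed=bool(g.attrs["smoothed"]))
                freqs[name][key] = float(g.attrs["pair_frequency"])
            out[name] = hists
    return PotentialTables(real=out["real"], random=out["random"],
                           pair_frequency_real=freqs["real"],
                           pair_frequency_random=freqs["random"],
                           definitions=defs,
                           floor_probability=None if floor < 0 else floor,
                           provenance=prov)
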