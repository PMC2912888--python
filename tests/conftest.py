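"""Shared fixtures: toy rotamer library, synthetic structures, planted
corpora and statistics tables. Everything is generated in-process from
seeds; nothing is downloaded or read from binary files."""
from __future__ import annotations

import logging

import pytest

import tetrapot as tp
from tetrapot import fixtures as fx

logging.disable(logging.WARNING)

HELIX_SEQ = "KNELWQRVFYMHDT"


@pytest.fixture(scope="session")
def toy_library():
    return fx.make_toy_rotamer_library(seed=1)


@pytest.fixture(scope="session")
def helix_native(toy_library):
    s = fx.make_toy_structure(HELIX_SEQ, seed=3, conformation="helix",
                              library=toy_library, structure_id="native")
    return tp.assign_lj_classes(s)


@pytest.fixture(scope="session")
def helix_corpus(toy_library):
    return [fx.make_toy_structure(HELIX_SEQ, seed=100 + k, conformation="helix",
                                  library=toy_library, structure_id=f"c{k}")
            for k in range(8)]


@pytest.fixture(scope="session")
def helix_tables(helix_corpus, toy_library):
    defs = tp.select_atom_pairs(helix_corpus)
    defs.update(tp.default_scmc_definitions(defs))
    return tp.build_statistics(helix_corpus, defs, toy_library, rng_seed=7)


@pytest.fixture(scope="session")
def lj_params():
    return tp.load_lj_params()


@pytest.fixture(scope="session")
def planted_quadruple():
    return fx.feasible_quadruple(("ASN", "GLN"))


@pytest.fixture(scope="session")
def planted_corpus(planted_quadruple):
    spec = fx.PlantedGeometrySpec(pair=("ASN", "GLN"),
                                  quadruple=planted_quadruple,
                                  n_signal=500, n_noise=500,
                                  jitter=0.1, seed=9)
    return fx.make_planted_corpus(spec)


@pytest.fixture(scope="session")
def planted_tables(planted_corpus, toy_library):
    defs = {planted_corpus.definition.pair: planted_corpus.definition}
    return tp.build_statistics(planted_corpus.structures, defs, toy_library,
                               rng_seed=3)


def planted_native(quadruple, seed, n_pairs=4):
    """One structure holding ``n_pairs`` planted-geometry Asn-Gln contacts
    on distinct chain pairs."""
    from tetrapot.structure_model import Structure
    sub = fx.make_planted_corpus(fx.PlantedGeometrySpec(
        pair=("ASN", "GLN"), quadruple=quadruple,
        n_signal=n_pairs, n_noise=0, jitter=0.0, seed=seed))
    residues = []
    for si, st in enumerate(sub.structures):
        for r in st.residues:
            r.chain_id = chr(ord("A") + 2 * si + (0 if r.chain_id == "A" else 1))
            residues.append(r)
    return Structure(id=f"planted_native_{seed}", residues=residues)
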