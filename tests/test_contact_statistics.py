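"""Four-distance contact harvesting, histograms, smoothing and the
randomized-rotamer reference."""
import numpy as np
import pytest

import tetrapot as tp
from tetrapot import constants as C
from tetrapot import fixtures as fx
from tetrapot.contact_statistics import (AtomPairDefinition,
                                         FourDistanceContact, MAINCHAIN,
                                         _pair_choices, build_histogram,
                                         enumerate_candidates,
                                         extract_contacts, scmc_pair_keys,
                                         scsc_pair_keys, select_atom_pairs,
                                         smooth_histogram)
from tetrapot.errors import ParameterError
from tetrapot.structure_model import Atom, Residue, Structure


def _bare_residue(res_type, chain, seq, named_coords):
    """A hand-placed residue: backbone CA plus explicitly positioned atoms."""
    atoms = [Atom(name="CA", element="C",
                  coords=named_coords.get("CA", np.zeros(3)), is_backbone=True)]
    for name, xyz in named_coords.items():
        if name == "CA":
            continue
        atoms.append(Atom(name=name, element=C.element_of(name),
                          coords=np.asarray(xyz, float),
                          is_backbone=name in C.BACKBONE_ATOMS))
    return Residue(type=res_type, chain_id=chain, seq_id=seq, atoms=atoms)


ASN_DEF = AtomPairDefinition(pair=("ASN", "ASN"), atoms_a=("OD1", "ND2"),
                             atoms_b=("OD1", "ND2"))


def _two_asn(min_distance):
    """Two Asn residues whose closest definition distance equals exactly
    ``min_distance`` (other distances larger)."""
    r1 = _bare_residue("ASN", "A", 1, {"CA": (0, 0, 0), "OD1": (0, 0, 0),
                                       "ND2": (2.25, 0, 0)})
    r2 = _bare_residue("ASN", "B", 1, {"CA": (0, min_distance + 3, 0),
                                       "OD1": (0, min_distance, 0),
                                       "ND2": (2.25, min_distance + 1.0, 0)})
    return Structure(id="pair", residues=[r1, r2])


class TestCandidates:
    def test_asn_gln_has_60_combinations(self):
        assert len(enumerate_candidates("ASN", "GLN")) == 60

    def test_gly_ala_empty(self):
        assert enumerate_candidates("GLY", "ALA") == []

    def test_cys_cys_single_combination(self):
        assert enumerate_candidates("CYS", "CYS") == [(("CB", "SG"), ("CB", "SG"))]

    def test_ala_uses_ca_cb_pair(self):
        assert _pair_choices("ALA") == [("CA", "CB")]

    def test_pair_type_counts(self):
        assert len(scsc_pair_keys()) == 190
        assert len(scmc_pair_keys()) == 18


class TestExtract:
    def test_contact_strictly_below_cutoff(self):
        s = _two_asn(4.9)
        assert len(extract_contacts(s, {ASN_DEF.pair: ASN_DEF})) == 1

    def test_no_contact_at_cutoff(self):
        s = _two_asn(5.0)
        assert extract_contacts(s, {ASN_DEF.pair: ASN_DEF}) == []

    def test_sequence_neighbours_excluded(self):
        s = _two_asn(3.0)
        for r in s.residues:
            r.chain_id = "A"
        s.residues[1].seq_id = 2
        assert extract_contacts(s, {ASN_DEF.pair: ASN_DEF}) == []

    def test_planted_contacts_reproduce_quadruples(self, planted_quadruple):
        pc = fx.make_planted_corpus(fx.PlantedGeometrySpec(
            pair=("ASN", "GLN"), quadruple=planted_quadruple,
            n_signal=3, n_noise=0, jitter=0.0, seed=2))
        defs = {pc.definition.pair: pc.definition}
        records = []
        for s in pc.structures:
            records += extract_contacts(s, defs)
        assert len(records) == 3
        for c in records:
            np.testing.assert_allclose(c.quadruple, planted_quadruple,
                                       atol=1e-6)

    def test_missing_contact_atom_skips_pair(self):
        s = _two_asn(3.0)
        s.residues[1].atoms = [a for a in s.residues[1].atoms
                               if a.name != "ND2"]
        assert extract_contacts(s, {ASN_DEF.pair: ASN_DEF}) == []


class TestSelect:
    def test_only_contacting_choices_counted(self):
        # only Asn ND2 is within 5 A of the Cys pair; the 3 Asn choices
        # containing ND2 tie at one contact and the lexicographically
        # smallest, (CB, ND2), must win
        r1 = _bare_residue("CYS", "A", 1, {"CA": (0, 0, 0), "CB": (0, 0, 0),
                                           "SG": (1.8, 0, 0)})
        r2 = _bare_residue("ASN", "B", 1, {
            "CA": (0, 4.0, 0), "ND2": (0, 4.0, 0), "OD1": (0, 9.5, 0),
            "CB": (0, 12.0, 0), "CG": (0, 10.5, 0)})
        defs = select_atom_pairs([Structure(id="s", residues=[r1, r2])])
        d = defs[("ASN", "CYS")]
        assert d.pair == ("ASN", "CYS")
        assert d.atoms_a == ("CB", "ND2")
        assert d.atoms_b == ("CB", "SG")

    def test_tie_breaks_lexicographically(self):
        # both combinations of a Cys-Ser pair contact equally often
        r1 = _bare_residue("CYS", "A", 1, {"CA": (0, 0, 0), "CB": (0, 0, 0),
                                           "SG": (1.8, 0, 0)})
        r2 = _bare_residue("SER", "B", 1, {"CA": (0, 3, 0), "CB": (0, 3, 0),
                                           "OG": (1.4, 3, 0)})
        defs = select_atom_pairs([Structure(id="s", residues=[r1, r2])])
        d = defs[("CYS", "SER")]
        assert d.atoms_a == ("CB", "SG") and d.atoms_b == ("CB", "OG")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ParameterError):
            select_atom_pairs([])

    def test_selection_maximises_contact_count(self, planted_corpus):
        defs = select_atom_pairs(planted_corpus.structures[:50])
        assert ("ASN", "GLN") in defs


class TestHistogram:
    def test_single_contact_binning(self):
        c = FourDistanceContact(("ASN", "ASN"), 2.8, 3.1, 3.3, 3.5)
        h = build_histogram([c])
        assert h.counts.shape == (20, 20, 20, 20)
        assert h.counts.sum() == 1
        assert h.probabilities[5, 6, 6, 7] == 1.0

    def test_grid_size(self):
        h = build_histogram([])
        assert h.n_bins == 20
        assert h.probabilities.size == 160000
        assert h.uninformative

    def test_three_to_one_split(self):
        cs = [FourDistanceContact(("ASN", "ASN"), 2.8, 3.1, 3.3, 3.5)] * 3
        cs += [FourDistanceContact(("ASN", "ASN"), 4.8, 3.1, 3.3, 3.5)]
        h = build_histogram(cs)
        assert h.probabilities[5, 6, 6, 7] == 0.75
        assert h.probabilities[9, 6, 6, 7] == 0.25

    def test_long_distances_clamped_into_last_bin(self):
        c = FourDistanceContact(("ASN", "ASN"), 2.8, 14.0, 10.0, 3.5)
        h = build_histogram([c])
        assert h.probabilities[5, 19, 19, 7] == 1.0

    def test_bin_size_must_divide_range(self):
        with pytest.raises(ParameterError):
            build_histogram([], bin_size=0.3)


def _direct_cross_smooth(p):
    """Independent oracle: literal evaluation of the axis-adjacent mean with
    boundary truncation, then renormalisation."""
    out = np.zeros_like(p)
    shape = p.shape
    for idx in np.ndindex(shape):
        vals = [p[idx]]
        for ax in range(p.ndim):
            for step in (-1, 1):
                j = list(idx)
                j[ax] += step
                if 0 <= j[ax] < shape[ax]:
                    vals.append(p[tuple(j)])
        out[idx] = np.mean(vals)
    return out / out.sum()


class TestSmoothing:
    def test_uniform_is_fixed_point(self):
        h = build_histogram([FourDistanceContact(("A", "A"), 1, 1, 1, 1)],
                            bin_size=2.5, max_distance=10.0)
        h.probabilities = np.full((4, 4, 4, 4), 1.0 / 256)
        sm = smooth_histogram(h)
        np.testing.assert_allclose(sm.probabilities, 1.0 / 256, atol=1e-12)

    def test_interior_point_mass_matches_direct_kernel(self):
        p = np.zeros((6, 6, 6, 6))
        p[3, 3, 3, 3] = 1.0
        h = build_histogram([], bin_size=0.5, max_distance=3.0)
        h.probabilities = p
        h.total_count = 1
        sm = smooth_histogram(h)
        np.testing.assert_allclose(sm.probabilities, _direct_cross_smooth(p),
                                   atol=1e-12)
        # mass spreads over the 9-cell cross, equally after renormalisation
        assert (sm.probabilities > 0).sum() == 9
        assert sm.probabilities[3, 3, 3, 3] == pytest.approx(1.0 / 9)

    def test_corner_point_mass_matches_direct_kernel(self):
        p = np.zeros((6, 6, 6, 6))
        p[0, 0, 0, 0] = 1.0
        h = build_histogram([], bin_size=0.5, max_distance=3.0)
        h.probabilities = p
        h.total_count = 1
        sm = smooth_histogram(h)
        np.testing.assert_allclose(sm.probabilities, _direct_cross_smooth(p),
                                   atol=1e-12)
        assert (sm.probabilities > 0).sum() == 5

    def test_double_smoothing_rejected(self):
        h = build_histogram([FourDistanceContact(("A", "A"), 1, 1, 1, 1)])
        sm = smooth_histogram(h)
        with pytest.raises(ParameterError):
            smooth_histogram(sm)

    def test_mass_conserved(self, planted_corpus):
        defs = {planted_corpus.definition.pair: planted_corpus.definition}
        contacts = extract_contacts(planted_corpus.structures[0], defs)
        for s in planted_corpus.structures[1:40]:
            contacts += extract_contacts(s, defs)
        h = build_histogram(contacts)
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        sm = smooth_histogram(h)
        assert sm.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestRandomize:
    def test_gly_ala_essentially_unchanged(self, toy_library):
        s = fx.make_toy_structure("GAGA", seed=4, library=toy_library)
        r = tp.randomize_side_chains(s, toy_library, rng_seed=1)
        for orig, rand in zip(s.residues, r.residues):
            for a, b in zip(orig.atoms, rand.atoms):
                np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    def test_seed_determinism(self, helix_native, toy_library):
        a = tp.randomize_side_chains(helix_native, toy_library, rng_seed=5)
        b = tp.randomize_side_chains(helix_native, toy_library, rng_seed=5)
        for ra, rb in zip(a.residues, b.residues):
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.array_equal(x.coords, y.coords)

    def test_single_rotamer_library_is_seed_independent(self, helix_native):
        from tetrapot.rotamer_library import Rotamer, RotamerLibrary
        lib = RotamerLibrary(grid=360.0, entries={})
        for res in C.AMINO_ACIDS:
            n = C.N_CHI[res]
            if n:
                lib.entries[(res, 0, 0)] = [
                    Rotamer(res, (-60.0,) + (180.0,) * (n - 1), (8.0,) * n, 1.0)]
        a = tp.randomize_side_chains(helix_native, lib, rng_seed=1)
        b = tp.randomize_side_chains(helix_native, lib, rng_seed=99)
        for ra, rb in zip(a.residues, b.residues):
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.array_equal(x.coords, y.coords)

    def test_backbone_untouched(self, helix_native, toy_library):
        r = tp.randomize_side_chains(helix_native, toy_library, rng_seed=2)
        for orig, rand in zip(helix_native.residues, r.residues):
            for name in ("N", "CA", "C", "O"):
                np.testing.assert_allclose(orig.atom(name).coords,
                                           rand.atom(name).coords, atol=1e-12)


class TestBuildStatistics:
    def test_planted_peak_dominates_reference(self, planted_corpus,
                                              planted_tables,
                                              planted_quadruple):
        key = planted_corpus.definition.pair
        real = planted_tables.real[key]
        rand = planted_tables.random[key]
        planted_bin = real.bin_index(planted_quadruple)
        assert real.probabilities[planted_bin] > 3 * rand.probabilities.max()

    def test_smoothed_argmax_is_planted_bin(self, planted_tables,
                                            planted_corpus,
                                            planted_quadruple):
        real = planted_tables.real[planted_corpus.definition.pair]
        assert real.smoothed
        argmax = np.unravel_index(real.probabilities.argmax(),
                                  real.probabilities.shape)
        assert argmax == real.bin_index(planted_quadruple)

    def test_pair_frequencies_normalised(self, helix_tables):
        for fam in (False, True):
            keys = [k for k, d in helix_tables.definitions.items()
                    if d.is_scmc == fam and k in helix_tables.pair_frequency_real]
            for freqs in (helix_tables.pair_frequency_real,
                          helix_tables.pair_frequency_random):
                total = sum(freqs[k] for k in keys)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_determinism(self, planted_corpus, toy_library):
        defs = {planted_corpus.definition.pair: planted_corpus.definition}
        sub = planted_corpus.structures[:60]
        t1 = tp.build_statistics(sub, defs, toy_library, rng_seed=11)
        t2 = tp.build_statistics(sub, defs, toy_library, rng_seed=11)
        k = planted_corpus.definition.pair
        assert np.array_equal(t1.real[k].counts, t2.real[k].counts)
        assert np.array_equal(t1.random[k].counts, t2.random[k].counts)

    def test_homotypic_table_is_swap_symmetric(self, toy_library):
        quad = fx.feasible_quadruple(("ASN", "ASN"))
        pc = fx.make_planted_corpus(fx.PlantedGeometrySpec(
            pair=("ASN", "ASN"), quadruple=quad, n_signal=60, n_noise=60,
            jitter=0.2, seed=4))
        tables = tp.build_statistics(pc.structures,
                                     {pc.definition.pair: pc.definition},
                                     toy_library, rng_seed=1, smooth=False)
        p = tables.real[("ASN", "ASN")].probabilities
        # swapping the residues maps (d11,d12,d21,d22) -> (d11,d21,d12,d22)
        np.testing.assert_allclose(p, p.transpose(0, 2, 1, 3), atol=1e-12)
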