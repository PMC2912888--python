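"""The four energy terms, their invariances and incremental consistency."""
import math

import numpy as np
import pytest

import tetrapot as tp
from tetrapot import constants as C
from tetrapot import fixtures as fx
from tetrapot._geom import random_rotation
from tetrapot.contact_statistics import Histogram4D, PotentialTables
from tetrapot.errors import ParameterError
from tetrapot.potential import lj_pair_energy, rotamer_log_term
from tetrapot.rotamer_library import Rotamer


def _uniform_tables(definition):
    """Tables where real and random agree exactly: every contact scores 0."""
    n = 20
    p = np.full((n, n, n, n), 1.0 / n ** 4)
    mk = lambda: Histogram4D(pair_key=definition.pair, bin_size=0.5,
                             max_distance=10.0,
                             counts=np.ones((n, n, n, n), dtype=np.int64),
                             probabilities=p.copy(), total_count=n ** 4,
                             smoothed=False)
    return PotentialTables(real={definition.pair: mk()},
                           random={definition.pair: mk()},
                           pair_frequency_real={definition.pair: 1.0},
                           pair_frequency_random={definition.pair: 1.0},
                           definitions={definition.pair: definition})


class TestLogRatioTerms:
    def test_identical_distributions_score_zero(self, planted_corpus):
        tables = _uniform_tables(planted_corpus.definition)
        score, n = tp.score_scsc(planted_corpus.structures[0], tables)
        assert n == 1
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_planted_structures_score_favourably(self, planted_corpus,
                                                 planted_tables, toy_library):
        native = planted_corpus.structures[0]  # a signal structure
        score, n = tp.score_scsc(native, planted_tables)
        assert n == 1
        assert score < 0
        scrambled = tp.randomize_side_chains(native, toy_library, rng_seed=8)
        s2, _ = tp.score_scsc(scrambled, planted_tables)
        assert s2 > score

    def test_empty_bin_is_penalised(self, planted_corpus, planted_tables):
        # a noise-free quadruple placed in a bin with real mass gets a bonus;
        # force an off-peak contact by mirroring one noise structure far away
        key = planted_corpus.definition.pair
        real = planted_tables.real[key]
        rand = planted_tables.random[key]
        floor = planted_tables.floor_for(key)
        # find a bin populated in the reference but empty in the real table
        candidates = np.argwhere((real.probabilities == 0.0)
                                 & (rand.probabilities > floor))
        assert len(candidates) > 0
        idx = tuple(candidates[0])
        pq = float(rand.probabilities[idx])
        fr = max(planted_tables.pair_frequency_real[key], floor)
        fq = max(planted_tables.pair_frequency_random[key], floor)
        contribution = -math.log((floor * fr) / (pq * fq))
        assert contribution > 0

    def test_no_contacts_scores_zero(self, helix_tables, toy_library):
        s = fx.make_toy_structure("GG", seed=0, library=toy_library)
        assert tp.score_scsc(s, helix_tables) == (0.0, 0)
        assert tp.score_scmc(s, helix_tables) == (0.0, 0)

    def test_scmc_counts_contacts(self, helix_native, helix_tables):
        score, n = tp.score_scmc(helix_native, helix_tables)
        assert n > 0


class TestRotamerTerm:
    def test_uniform_group_scores_zero(self):
        group = [Rotamer("SER", (60.0 * k,), (8.0,), 0.25) for k in range(4)]
        assert rotamer_log_term(group[1], group) == pytest.approx(0.0)

    def test_single_rotamer_scores_zero(self):
        group = [Rotamer("SER", (60.0,), (8.0,), 1.0)]
        assert rotamer_log_term(group[0], group) == pytest.approx(0.0)

    def test_above_uniform_probability_is_favourable(self):
        group = [Rotamer("SER", (60.0,), (8.0,), 0.5)] + [
            Rotamer("SER", (-60.0 + k,), (8.0,), 0.5 / 3) for k in range(3)]
        assert rotamer_log_term(group[0], group) == pytest.approx(-math.log(2.0))

    def test_foreign_rotamer_rejected(self):
        group = [Rotamer("SER", (60.0,), (8.0,), 1.0)]
        with pytest.raises(ParameterError):
            rotamer_log_term(Rotamer("SER", (170.0,), (8.0,), 0.5), group)


class TestLennardJones:
    def test_minimum_energy_at_rmin(self):
        e = lj_pair_energy(np.array([3.4]), np.array([0.2]), np.array([3.4]))
        assert e[0] == pytest.approx(-0.2)

    def test_linearization_continuity(self):
        eps, rmin = 0.15, 3.6
        d0 = 0.89 * rmin
        h = 1e-7
        below = lj_pair_energy(np.array([d0 - h]), np.array([eps]),
                               np.array([rmin]))[0]
        above = lj_pair_energy(np.array([d0 + h]), np.array([eps]),
                               np.array([rmin]))[0]
        assert below == pytest.approx(above, abs=1e-4)
        # matching slopes: second difference across the joint is tiny
        d = np.array([d0 - 2 * h, d0 - h, d0, d0 + h, d0 + 2 * h])
        e = lj_pair_energy(d, np.full(5, eps), np.full(5, rmin))
        slopes = np.diff(e) / h
        assert slopes[0] == pytest.approx(slopes[-1], rel=1e-3)

    def test_linear_branch_caps_repulsion(self):
        eps, rmin = 0.15, 3.6
        d = np.array([0.5 * rmin])
        capped = lj_pair_energy(d, np.array([eps]), np.array([rmin]))[0]
        raw = eps * ((rmin / d[0]) ** 12 - 2 * (rmin / d[0]) ** 6)
        assert capped < raw

    def test_sign_split(self, helix_native, lj_params):
        e_lja, e_ljr = tp.score_lj(helix_native, lj_params)
        assert e_lja <= 0
        assert e_ljr >= 0

    def test_backbone_only_chain_scores_zero(self, toy_library, lj_params):
        s = fx.make_toy_structure("GGGG", seed=0, library=toy_library)
        tp.assign_lj_classes(s)
        assert tp.score_lj(s, lj_params) == (0.0, 0.0)


class TestTotal:
    def test_weight_projection(self, helix_native, helix_tables, lj_params):
        br = tp.total_score(helix_native, helix_tables, None, lj_params,
                            tp.Weights(1.0, 0.0, 0.0, 0.0))
        assert br.total == pytest.approx(br.e_scsc, abs=1e-12)

    def test_total_is_weighted_dot_product(self, helix_native, helix_tables,
                                           lj_params):
        w = tp.Weights()
        br = tp.total_score(helix_native, helix_tables, None, lj_params, w)
        expected = (w.w_scsc * br.e_scsc + w.w_scmc * br.e_scmc
                    + w.w_rot * br.e_rot + w.w_lj * (br.e_lja + br.e_ljr))
        assert br.total == pytest.approx(expected, abs=1e-9)

    def test_negative_weight_rejected(self):
        with pytest.raises(ParameterError):
            tp.Weights(-0.1, 0.1, 0.1, 0.1)

    def test_rigid_motion_invariance(self, helix_native, helix_tables,
                                     lj_params):
        rng = np.random.default_rng(0)
        rot = random_rotation(rng)
        shift = rng.uniform(-20, 20, 3)
        moved = helix_native.copy()
        for r in moved.residues:
            for a in r.atoms:
                a.coords = rot @ a.coords + shift
        from tetrapot.structure_model import compute_backbone_dihedrals
        compute_backbone_dihedrals(moved)
        b0 = tp.total_score(helix_native, helix_tables, None, lj_params)
        b1 = tp.total_score(moved, helix_tables, None, lj_params)
        assert b1.total == pytest.approx(b0.total, abs=1e-6)
        assert b1.e_scsc == pytest.approx(b0.e_scsc, abs=1e-6)
        assert b1.e_ljr == pytest.approx(b0.e_ljr, abs=1e-6)

    def test_chain_relabel_invariance(self, helix_native, helix_tables,
                                      lj_params):
        relabeled = helix_native.copy()
        for r in relabeled.residues:
            r.chain_id = "Q"
        b0 = tp.total_score(helix_native, helix_tables, None, lj_params)
        b1 = tp.total_score(relabeled, helix_tables, None, lj_params)
        assert b1.total == pytest.approx(b0.total, abs=1e-9)


class TestIncrementalConsistency:
    def test_delta_matches_full_rescore(self, helix_native, helix_tables,
                                        toy_library, lj_params):
        model = tp.EnergyModel(helix_native, helix_tables, toy_library,
                               lj_params)
        rng = np.random.default_rng(3)
        positions = model.positions
        assignment = {}
        for i in positions:
            g = model.groups[i]
            from dataclasses import replace
            k = int(rng.integers(len(g)))
            assignment[i] = replace(g[k], origin=k)
        base = model.total(assignment)
        for trial in range(6):
            from dataclasses import replace
            pos = positions[int(rng.integers(len(positions)))]
            g = model.groups[pos]
            k = int(rng.integers(len(g)))
            cand = replace(g[k], origin=k)
            de = model.delta(assignment, pos, cand)
            new_assignment = dict(assignment)
            new_assignment[pos] = cand
            full = model.total(new_assignment)
            assert base + de == pytest.approx(full, abs=1e-6)
            model.apply(assignment)  # restore working structure
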