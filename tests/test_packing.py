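"""Monte Carlo simulated annealing, quench and best-rotameric construction."""
import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

import tetrapot as tp
from tetrapot import constants as C
from tetrapot import fixtures as fx
from tetrapot.errors import TetrapotError
from tetrapot.packing import _mutable_positions
from tetrapot.rotamer_library import Rotamer, RotamerLibrary


def _toy_system(n_positions, group_sizes, seed=0):
    """A small structure + library + pairwise-coupled tabulated scorer.

    The scorer is a random symmetric pairwise energy over rotamer indices —
    cheap and exhaustively enumerable."""
    seq = "".join(["S", "C", "T", "V", "S", "C"][:n_positions])
    lib = RotamerLibrary(grid=360.0, entries={})
    rng = np.random.default_rng(seed)
    structure = fx.make_toy_structure(seq + "G", seed=seed)
    for pos, (ch, size) in enumerate(zip(seq, group_sizes)):
        rt = C.ONE_TO_THREE[ch]
        lib.entries[(rt, 0, 0)] = [
            Rotamer(rt, (-170.0 + 40 * k,), (8.0,), 1.0 / size)
            for k in range(size)]
    # grid=360 -> one bin; groups keyed by residue type, so equal-size groups
    # are shared across same-type positions (fine for the oracle test)
    single = rng.uniform(0, 2, (n_positions, max(group_sizes)))
    pair = rng.uniform(-1, 1, (n_positions, n_positions,
                               max(group_sizes), max(group_sizes)))

    def scorer(assignment):
        idx = {p: r.origin for p, r in assignment.items()}
        e = sum(single[p, k] for p, k in idx.items())
        for p, q in itertools.combinations(sorted(idx), 2):
            e += pair[p, q, idx[p], idx[q]]
        return float(e)

    groups = _mutable_positions(structure, lib)
    return structure, lib, scorer, groups


def _enumerate_minimum(scorer, groups):
    best = None
    positions = sorted(groups)
    for combo in itertools.product(*[range(len(groups[p])) for p in positions]):
        assignment = {p: replace(groups[p][k], origin=k)
                      for p, k in zip(positions, combo)}
        e = scorer(assignment)
        if best is None or e < best:
            best = e
    return best


class TestCalibrateTemperature:
    def test_constant_scorer_starts_at_one(self, toy_library, helix_native):
        rng = np.random.default_rng(0)
        T0 = tp.calibrate_temperature(lambda a: 0.0, helix_native,
                                      toy_library, rng)
        assert T0 == 1.0

    def test_bounded_deltas_terminate(self):
        structure, lib, scorer, groups = _toy_system(3, [3, 3, 3])
        rng = np.random.default_rng(1)
        T0 = tp.calibrate_temperature(scorer, structure, lib, rng)
        assert T0 >= 1.0

    def test_seed_determinism(self):
        structure, lib, scorer, _ = _toy_system(3, [4, 3, 4])
        a = tp.calibrate_temperature(scorer, structure, lib,
                                     np.random.default_rng(7))
        b = tp.calibrate_temperature(scorer, structure, lib,
                                     np.random.default_rng(7))
        assert a == b

    def test_pathological_scorer_raises(self, toy_library, helix_native):
        class InfiniteBarrier:
            def total(self, assignment):
                return 0.0

            def delta(self, assignment, pos, rot):
                return math.inf  # every substitution is infinitely bad

        rng = np.random.default_rng(0)
        with pytest.raises(TetrapotError):
            tp.calibrate_temperature(InfiniteBarrier(), helix_native,
                                     toy_library, rng, target=0.95,
                                     n_probe=50, max_doublings=10)


def _always_reject_scorer(assignment):
    # any change from the initial state costs +1e9 per differing position
    return 1e9 * sum(r.origin for r in assignment.values())


class TestMCSA:
    def test_single_residue_finds_argmin(self):
        structure, lib, _, groups = _toy_system(1, [3])
        values = [2.0, 0.5, 1.0]

        def scorer(assignment):
            (rot,) = assignment.values()
            return values[rot.origin]

        cfg = tp.MCSAConfig(cooling_steps=5, moves_per_step=30, rng_seed=0)
        result = tp.mcsa_pack(structure, scorer, lib, cfg)
        assert result.score == pytest.approx(0.5)
        (rot,) = result.assignment.values()
        assert rot.origin == 1

    def test_matches_exhaustive_enumeration(self):
        structure, lib, scorer, groups = _toy_system(3, [4, 3, 4], seed=5)
        target = _enumerate_minimum(scorer, groups)
        hits = 0
        for seed in range(20):
            cfg = tp.MCSAConfig(cooling_steps=15, moves_per_step=120,
                                rng_seed=seed)
            result = tp.mcsa_pack(structure, scorer, lib, cfg)
            assert result.score >= target - 1e-9  # never beats the oracle
            hits += abs(result.score - target) < 1e-9
        assert hits >= 18

    def test_seed_determinism(self):
        structure, lib, scorer, _ = _toy_system(3, [4, 4, 4], seed=2)
        cfg = tp.MCSAConfig(cooling_steps=10, moves_per_step=80, rng_seed=11)
        a = tp.mcsa_pack(structure, scorer, lib, cfg)
        b = tp.mcsa_pack(structure, scorer, lib, cfg)
        assert a.score == b.score
        assert {p: r.origin for p, r in a.assignment.items()} == \
               {p: r.origin for p, r in b.assignment.items()}

    def test_no_mutable_residues_returns_input(self, toy_library):
        structure = fx.make_toy_structure("GGGG", seed=0, library=toy_library)
        result = tp.mcsa_pack(structure, lambda a: 0.0, toy_library,
                              tp.MCSAConfig(cooling_steps=2, moves_per_step=5))
        assert result.assignment == {}
        assert len(result.structure) == 4

    def test_best_score_never_exceeds_accepted_after_warmup(self):
        structure, lib, scorer, _ = _toy_system(3, [4, 3, 4], seed=9)
        cfg = tp.MCSAConfig(cooling_steps=12, moves_per_step=60, rng_seed=3)
        result = tp.mcsa_pack(structure, scorer, lib, cfg)
        bests = [t["best"] for t in result.trajectory]
        assert all(b1 <= b0 + 1e-12 for b0, b1 in zip(bests, bests[1:]))
        assert result.score <= bests[-1] + 1e-12


class TestQuench:
    def test_reaches_local_optimum(self):
        structure, lib, scorer, groups = _toy_system(3, [4, 4, 4], seed=3)
        positions = sorted(groups)
        start = {p: replace(groups[p][0], origin=0) for p in positions}
        out = tp.quench(structure, start, scorer, lib)
        base = scorer(out)
        for p in positions:
            for k, r in enumerate(groups[p]):
                trial = dict(out)
                trial[p] = replace(r, origin=k)
                assert scorer(trial) >= base - 1e-12

    def test_fixed_point(self):
        structure, lib, scorer, groups = _toy_system(2, [3, 3], seed=4)
        positions = sorted(groups)
        start = {p: replace(groups[p][0], origin=0) for p in positions}
        once = tp.quench(structure, start, scorer, lib)
        twice = tp.quench(structure, once, scorer, lib)
        assert {p: r.origin for p, r in once.items()} == \
               {p: r.origin for p, r in twice.items()}

    def test_single_residue_reaches_global_optimum(self):
        structure, lib, _, groups = _toy_system(1, [5])
        values = [3.0, 2.0, 0.25, 1.0, 2.5]
        scorer = lambda a: values[next(iter(a.values())).origin]
        pos = next(iter(groups))
        start = {pos: replace(groups[pos][0], origin=0)}
        out = tp.quench(structure, start, scorer, lib)
        assert out[pos].origin == 2

    def test_score_non_increasing(self):
        structure, lib, scorer, groups = _toy_system(4, [4, 4, 4, 4], seed=6)
        trace = []
        def tracking(assignment):
            e = scorer(assignment)
            return e
        positions = sorted(groups)
        start = {p: replace(groups[p][-1], origin=len(groups[p]) - 1)
                 for p in positions}
        out = tp.quench(structure, start, tracking, lib)
        assert tracking(out) <= tracking(start) + 1e-12


class TestOffRotamer:
    def test_double_step_with_opposite_signs_restores(self):
        rot = Rotamer("SER", (60.0,), (8.0,), 1.0, origin=0)
        assignment = {0: rot}
        a1, pos = tp.off_rotamer_step(assignment, np.random.default_rng(0))
        delta = a1[pos].chi[0] - assignment[pos].chi[0]
        assert abs(delta) == pytest.approx(5.0)
        a2 = dict(a1)
        a2[pos] = replace(a1[pos], chi=(a1[pos].chi[0] - delta,))
        assert a2[pos].chi == assignment[pos].chi

    def test_seed_determinism(self):
        assignment = {0: Rotamer("SER", (60.0,), (8.0,), 1.0, origin=0),
                      1: Rotamer("LYS", (-60.0, 180.0, 180.0, 180.0),
                                 (8.0,) * 4, 1.0, origin=0)}
        a1, p1 = tp.off_rotamer_step(assignment, np.random.default_rng(5))
        a2, p2 = tp.off_rotamer_step(assignment, np.random.default_rng(5))
        assert p1 == p2
        assert a1[p1].chi == a2[p2].chi

    def test_perturbed_rotamer_keeps_library_probability(self):
        group = [Rotamer("SER", (60.0,), (8.0,), 0.7),
                 Rotamer("SER", (-60.0,), (8.0,), 0.3)]
        assignment = {0: replace(group[0], origin=0)}
        a1, pos = tp.off_rotamer_step(assignment, np.random.default_rng(1))
        from tetrapot.potential import rotamer_log_term
        assert rotamer_log_term(a1[pos], group) == pytest.approx(
            -math.log(2 * 0.7))


class TestBestRotameric:
    def test_library_built_native_recovered(self, toy_library):
        native = fx.make_toy_structure("SKNELQRVT", seed=12,
                                       library=toy_library)
        rebuilt = tp.best_rotameric(native, toy_library)
        assert tp.sidechain_rmsd(rebuilt, native) < 0.05

    def test_backbone_unchanged(self, helix_native, toy_library):
        rebuilt = tp.best_rotameric(helix_native, toy_library)
        for a, b in zip(helix_native.residues, rebuilt.residues):
            for name in ("N", "CA", "C", "O"):
                np.testing.assert_allclose(a.atom(name).coords,
                                           b.atom(name).coords, atol=1e-12)

    def test_truncated_side_chain_skipped(self, toy_library):
        native = fx.make_toy_structure("SKS", seed=1, library=toy_library)
        lys = native.residues[1]
        lys.atoms = [a for a in lys.atoms if a.name != "NZ"]
        rebuilt = tp.best_rotameric(native, toy_library)
        # the truncated Lys is left as-is (still no NZ)
        assert rebuilt.residues[1].atom("NZ") is None


class TestEnergyModelPacking:
    def test_repack_improves_over_random(self, helix_native, helix_tables,
                                         toy_library, lj_params):
        model = tp.EnergyModel(helix_native, helix_tables, toy_library,
                               lj_params)
        cfg = tp.MCSAConfig(cooling_steps=8, moves_per_step=80, rng_seed=1)
        result = tp.mcsa_pack(helix_native, model, toy_library, cfg)
        assert result.structure is not None
        assert result.breakdown is not None
        # the packed structure scores no worse than a random-rotamer start
        scrambled = tp.randomize_side_chains(helix_native, toy_library, 3)
        tp.assign_lj_classes(scrambled)
        random_score = tp.total_score(scrambled, helix_tables, None,
                                      lj_params).total
        packed_score = (result.breakdown.weights.w_scsc * result.breakdown.e_scsc
                        + result.breakdown.weights.w_scmc * result.breakdown.e_scmc
                        + result.breakdown.weights.w_lj * result.breakdown.e_lj)
        assert packed_score < random_score
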