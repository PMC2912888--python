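"""Calibration: recover LJ class radii and sweep term weights.

Part 1 fits per-class radii from synthetic contact-distance distributions
whose peaks are exact radius sums — the least-squares fit recovers the
generating radii to machine precision, and polar-polar pairs become r_min
overrides instead of entering the fit.

Part 2 runs the hierarchical lambda sweep with a transparent objective to
show how the four weights compose.
"""
import logging
import numpy as np

logging.getLogger("tetrapot").setLevel(logging.ERROR)

import tetrapot as tp
from tetrapot.calibration import DistanceDistribution, fit_lj_radii, fit_weights
from tetrapot.fixtures import make_toy_rotamer_library, make_toy_structure

# -- Part 1: radii ----------------------------------------------------------
true_radii = {f"K{i}": 1.5125 + 0.05 * i for i in range(6)}
polar = {c: c in ("K0", "K1") for c in true_radii}
bin_size = 0.05
edges = np.arange(0.0, 10.0 + bin_size / 2, bin_size)
dists = []
classes = sorted(true_radii)
for i, ci in enumerate(classes):
    for cj in classes[i:]:
        peak = true_radii[ci] + true_radii[cj]
        counts = np.zeros(len(edges) - 1, dtype=int)
        counts[int(peak / bin_size)] = 20000
        dists.append(DistanceDistribution((ci, cj), bin_size, counts, edges,
                                          20000))
radii, overrides = fit_lj_radii(dists, polar)
err = max(abs(radii[c] - r) for c, r in true_radii.items())
print(f"fitted {len(radii)} radii, max |error| = {err:.2e} A")
print(f"polar-polar overrides: {len(overrides)} "
      f"(e.g. {next(iter(sorted(overrides)))})")

# -- Part 2: weights --------------------------------------------------------
library = make_toy_rotamer_library(seed=1)
corpus = [make_toy_structure("KNELW", seed=k, library=library)
          for k in range(2)]
defs = tp.select_atom_pairs(corpus)
tables = tp.build_statistics(corpus, defs, library, rng_seed=0)


def objective(w):
    """Stand-in objective with a known optimum at w_rot-heavy weights."""
    return (w.w_rot - 0.6) ** 2 + (w.w_scsc - 0.2) ** 2 + w.w_scmc ** 2


w = fit_weights([], tables, library, tp.load_lj_params(), objective=objective)
print(f"swept weights: w_scsc={w.w_scsc:.2f} w_scmc={w.w_scmc:.2f} "
      f"w_rot={w.w_rot:.2f} w_lj={w.w_lj:.2f} "
      f"(sum={w.w_scsc + w.w_scmc + w.w_rot + w.w_lj:.2f})")
print("shipped defaults:", tp.DEFAULT_WEIGHTS)
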