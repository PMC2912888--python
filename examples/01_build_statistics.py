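"""Harvest four-distance statistics from a corpus with a planted geometry.

Generates 500 Asn-Gln contacts at one target distance quadruple (plus 500
random-geometry contacts), builds the real and randomized-reference 4-D
histograms, and shows that the smoothed real distribution peaks exactly at
the planted bin while the reference does not.
"""
import numpy as np

import tetrapot as tp
from tetrapot.fixtures import (PlantedGeometrySpec, feasible_quadruple,
                               make_planted_corpus, make_toy_rotamer_library)

quad = feasible_quadruple(("ASN", "GLN"))
print(f"planted quadruple (d11,d12,d21,d22): {np.round(quad, 3)} A")

corpus = make_planted_corpus(PlantedGeometrySpec(
    pair=("ASN", "GLN"), quadruple=quad, n_signal=500, n_noise=500,
    jitter=0.1, seed=0))
library = make_toy_rotamer_library(seed=0)
tables = tp.build_statistics(
    corpus.structures, {corpus.definition.pair: corpus.definition},
    library, rng_seed=0)

real = tables.real[corpus.definition.pair]
rand = tables.random[corpus.definition.pair]
argmax = np.unravel_index(real.probabilities.argmax(), real.probabilities.shape)
print(f"real histogram: {real.total_count} contacts, smoothed={real.smoothed}")
print(f"smoothed argmax bin {argmax} vs planted bin {real.bin_index(quad)}")
print(f"peak probability real {real.probabilities.max():.5f} "
      f"vs reference max {rand.probabilities.max():.5f}")
# The real distribution concentrates at the planted geometry; the
# randomized-rotamer reference is diffuse, which is what the log-ratio
# score exploits.
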