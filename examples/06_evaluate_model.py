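"""Evaluate a model against its native: RMSD splits, chi accuracy,
normalized RMSD and the 0-100 contact score.
"""
import numpy as np

import tetrapot as tp
from tetrapot.fixtures import make_toy_rotamer_library, make_toy_structure

library = make_toy_rotamer_library(seed=1)
native = make_toy_structure("KNELWQRVFYMHDT", seed=3, library=library)
model = tp.randomize_side_chains(native, library, rng_seed=5)

report = tp.evaluate(model, native, library)
print(f"side-chain RMSD (all):  {report.rmsd_all:.2f} A")
print(f"chi1 within +-15 deg:   {report.chi1_pct:.1f} %")
print(f"chi1+2 within +-15 deg: {report.chi12_pct:.1f} %")
print(f"contact score:          {report.contact_score:.1f} / 100")
nr = [v for v in report.nrmsd.values() if v is not None]
print(f"median nRMSD:           {np.median(nr):.2f} "
      "(1.0 = random placement)")
print(f"self-evaluation sanity: contact score = "
      f"{tp.contact_score(native, native):.0f}")
# nRMSD compares each residue's error to the expected error of random
# rotamer placement (~1 = random level, <1 = better than random); the self
# contact score of 100 is the metric's fixed point.
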