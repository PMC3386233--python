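"""Detect tissue-state-sensitive probesets with SAM-FDR, plus qPCR checks.

Implants log2 shifts into a paired normal/tumor dataset, runs the
permutation SAM procedure with the 2^6 detection filter and a 20% FDR
cutoff, and evaluates the qPCR relative-expression formulas used to
confirm promoter calls.
"""

import numpy as np
import pandas as pd

from hervarray import fc_u5_u3, sam_fdr, tissue_specific_sets

rng = np.random.default_rng(61)
n_probesets, n_pairs = 600, 6
base = rng.uniform(7, 9, size=n_probesets)
log2 = base[:, None] + rng.normal(0, 1.0, size=(n_probesets, 2 * n_pairs))
log2[:40, n_pairs:] += 3.0  # tumor up-shift in the first 40 probesets
cols = [f"n{i}" for i in range(n_pairs)] + [f"t{i}" for i in range(n_pairs)]
expr = pd.DataFrame(2.0**log2, index=[f"ps{i}" for i in range(n_probesets)], columns=cols)
groups = pd.Series(["normal"] * n_pairs + ["tumor"] * n_pairs, index=cols)
pairs = pd.Series([f"p{i}" for i in range(n_pairs)] * 2, index=cols)

result = sam_fdr(expr, groups, paired=pairs, n_permutations=200, seed=0)
called = result.table.index[result.table["called"]]
truth = {f"ps{i}" for i in range(40)}
print(f"{len(called)} probesets called at FDR 20% "
      f"({len(result.filtered_out)} filtered below 2^6); "
      f"recall {len(set(called) & truth) / 40:.0%}, s0 = {result.s0:.3f}")

specific = tissue_specific_sets({"testis": set(called[:30]), "colon": set(called[20:])})
print(f"tissue-exclusive calls: testis {len(specific['testis'])}, "
      f"colon {len(specific['colon'])}")

ratio, promoter = fc_u5_u3(eff_u3=2.0, ct_u3=25.0, eff_u5=2.0, ct_u5=22.0)
print(f"\nqPCR confirmation: Fc_U5/U3 = {ratio:.0f} -> "
      f"{'promoter activity' if promoter else 'no promoter activity'}")
print("A U5 product appearing 3 cycles earlier than U3 at efficiency 2 means an")
print("8-fold U5 excess: transcription starts inside the LTR.")
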