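"""The three taxometric curves and their base-rate estimates.

Runs MAMBAC (50 cuts, trim 25), MAXEIG (50 windows, 90% overlap) and
L-Mode on a synthetic taxonic sample, and prints the shape summaries a
taxometrician reads off the plots, plus each procedure's taxon base-rate
estimate.
"""

import numpy as np

from taxometrics import (
    estimate_base_rate,
    lmode_scores,
    mambac_averaged,
    maxeig_averaged,
)
from taxometrics.simulate import anbp_scenario, make_taxonic

matrix = make_taxonic(anbp_scenario(), seed=1).matrix

mambac = mambac_averaged(matrix, n_cuts=50, trim=25, seed=0)
maxeig = maxeig_averaged(matrix, n_windows=50, overlap=0.90, seed=0)
lmode = lmode_scores(matrix)

peak_rank = int(mambac.x[np.argmax(mambac.mean_y)])
print(f"MAMBAC: {len(mambac.member_curves)} member curves (all ordered pairs); "
      f"peak at case rank {peak_rank} of {matrix.n_cases} "
      f"(cut {int(np.argmax(mambac.mean_y)) + 1} of 50)")
print(f"MAXEIG: {len(maxeig.member_curves)} member curves (each indicator as "
      f"input); peak at window {int(np.argmax(maxeig.mean_y)) + 1} of 50")
print(f"L-Mode: modes at {lmode.left_mode:.2f} and {lmode.right_mode:.2f} "
      f"(factor-score SD units), antimode at {lmode.antimode:.2f}")
print()
for result in (mambac, maxeig, lmode):
    br = estimate_base_rate(result)
    values = "/".join(f"{e:.3f}" for e in br.estimates)
    print(f"  {br.procedure:<7s} base rate {values}  [{', '.join(br.methods)}]"
          f"{'' if br.reliable else '  (flagged unreliable)'}")
print()
print("A peaked MAMBAC/MAXEIG curve and a bimodal factor-score density are")
print("the taxonic signatures; the generating taxon base rate is 0.101, and")
print("the L-Mode antimode split recovers it most directly.")
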