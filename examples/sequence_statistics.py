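"""Per-read composition, base-transition matrix and string autocorrelation.

A (GT)n read shows A/C-free composition, deterministic G->T / T->G
transitions, and autocorrelation peaks at even lags — the periodicity
signature by which repetitive reads stand out in heatmaps.
"""

import numpy as np

from doodlekit.seqstats import (
    BASES,
    autocorrelation_profile,
    base_composition,
    transition_matrix,
)

read = "GT" * 40

comp = base_composition(read)
print("composition:", {b: round(v, 2) for b, v in comp.as_dict().items()})

tm = transition_matrix(read)
print("transition matrix rows (A,C,G,T):")
for b, row in zip(BASES, tm.probabilities):
    print(f"  {b} ->", np.round(row, 2))

prof = autocorrelation_profile(read, max_lag=8)
print("r(k), k=0..8:", np.round(prof.r, 3))
# r(2), r(4), ... near 1 and odd lags at 0: period-2 tandem repeat. The
# slight decay at larger even lags is the finite-length /N normalization.
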