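"""Crisp domain decomposition by the two-stage Monte Carlo search.

Clusters a block-structured STDDV matrix for several cluster counts and
prints the achieved target function q, cluster sizes, and the
within/between dispersion table for the planted block count.
"""

import numpy as np

from semirigid import (
    SearchConfig,
    generate_block_matrix,
    mc_cluster,
    normalized_summary,
    within_between_table,
)

s, truth = generate_block_matrix((15, 9, 6), within_range=(0.05, 0.15),
                                 between_range=(0.6, 1.0), seed=1)

for k in range(1, 7):
    out = mc_cluster(s, k, SearchConfig(restarts=40, seed=0))
    summary = normalized_summary(s, out)
    print(f"n_clust={k}: q = {out.q:8.3f} nm, sizes = {out.sizes.tolist()}, "
          f"captured fraction = {summary.captured_fraction:.4f}")
# q falls monotonically with the cluster count; at the planted count (3)
# the sizes 15/9/6 reappear and only ~3% of the total pair variability
# remains inside clusters.

out = mc_cluster(s, 3, SearchConfig(restarts=40, seed=0))
table = within_between_table(s, out)
print("\nwithin/between mean STDDV [nm] at n_clust = 3:")
print(np.array_str(table, precision=3))
# Diagonal entries (within clusters) sit in the 0.05-0.15 band the blocks
# were built from; off-diagonal (between) entries in the 0.6-1.0 band.
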