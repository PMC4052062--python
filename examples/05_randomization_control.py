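"""Randomization control: does the matrix carry real structure?

Scrambling the pair values of S destroys any block structure while keeping
the value distribution.  Comparing cluster sizes and captured-STDDV
fractions between the original and the scrambled matrix separates genuine
motile dependencies from chance.
"""

from semirigid import (
    SearchConfig,
    generate_block_matrix,
    mc_cluster,
    normalized_summary,
    randomize_matrix,
)

s, _ = generate_block_matrix((15, 9, 6), (0.05, 0.15), (0.6, 1.0), seed=2)
r = randomize_matrix(s, seed=0)

print("n_clust  captured(structured)  captured(randomized)  sizes(structured)")
for k in range(2, 7):
    out_s = mc_cluster(s, k, SearchConfig(restarts=40, seed=0))
    out_r = mc_cluster(r, k, SearchConfig(restarts=40, seed=0))
    frac_s = normalized_summary(s, out_s).captured_fraction
    frac_r = normalized_summary(r, out_r).captured_fraction
    print(f"{k:7d}  {frac_s:20.4f}  {frac_r:20.4f}  {out_s.sizes.tolist()}")
# The structured matrix lets clustering shed far more pair variability at
# every cluster count, and its cluster sizes are unequal (they track the
# planted blocks); the scrambled control clusters into near-equal sizes
# and captures much less reduction — unequal sizes do not arise by chance.
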